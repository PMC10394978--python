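"""Core domain types for annotated song corpora.

A *syllable* is the smallest consistently repeated unit of song, represented
here as an opaque type label on a time interval.  A *song* is an ordered,
non-overlapping sequence of syllable tokens; a *corpus* is one individual's
analyzed songs together with its sex, hormone treatment and optional anatomy
covariates (volumes of the vocal control nuclei HVC, RA and Area X, and body
mass).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

SEXES = ("male", "female")
TREATMENTS = ("T", "T+E2", "control")

#: tolerance (s) when checking interval ordering; times are stored at ms precision
TIME_EPS = 1e-6


class SongSyntaxError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(SongSyntaxError):
    """A file could not be parsed in the expected format."""


class TierNotFoundError(ParseError):
    """The requested TextGrid tier does not exist in the file."""


class ValidationError(SongSyntaxError):
    """Input data violate a structural invariant (overlap, ordering, labels)."""


class InsufficientDataError(SongSyntaxError):
    """Too few observations to compute the requested quantity."""


def _normalize_sex(value: str) -> str:
    v = value.strip().lower()
    aliases = {"m": "male", "f": "female", "male": "male", "female": "female"}
    if v not in aliases:
        raise ValidationError(f"unknown sex value: {value!r} (expected male/female)")
    return aliases[v]


def _normalize_treatment(value: str) -> str:
    v = value.strip()
    aliases = {"T": "T", "T+E2": "T+E2", "TE2": "T+E2", "control": "control", "C": "control"}
    if v not in aliases:
        raise ValidationError(
            f"unknown treatment value: {value!r} (expected T, T+E2 or control)"
        )
    return aliases[v]


@dataclass(frozen=True)
class SyllableToken:
    """One annotated syllable: a non-empty type label on a time interval.

    ``onset``/``offset`` are in seconds.  Untimed tokens (sequence-only data)
    carry ``None`` for both; rate metrics are then unavailable downstream.
    """

    label: str
    onset: float | None = None
    offset: float | None = None

    def __post_init__(self) -> None:
        if not self.label:
            raise ValidationError("syllable label must be non-empty")
        if (self.onset is None) != (self.offset is None):
            raise ValidationError("onset and offset must both be given or both absent")
        if self.onset is not None and self.offset is not None:
            if not (self.offset > self.onset):
                raise ValidationError(
                    f"syllable {self.label!r}: offset ({self.offset}) must exceed "
                    f"onset ({self.onset})"
                )

    @property
    def timed(self) -> bool:
        return self.onset is not None


@dataclass(frozen=True)
class Song:
    """An ordered sequence of non-overlapping syllable tokens."""

    tokens: tuple[SyllableToken, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "tokens", tuple(self.tokens))
        prev: SyllableToken | None = None
        for tok in self.tokens:
            if prev is not None and prev.timed and tok.timed:
                if tok.onset < prev.offset - TIME_EPS:
                    raise ValidationError(
                        f"overlapping syllables: {prev.label!r} ends at {prev.offset} "
                        f"but {tok.label!r} starts at {tok.onset}"
                    )
            prev = tok

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(t.label for t in self.tokens)

    @property
    def timed(self) -> bool:
        return bool(self.tokens) and all(t.timed for t in self.tokens)

    @property
    def duration(self) -> float:
        """Song duration in seconds: last offset minus first onset.

        ``nan`` when the song is empty or any token is untimed.
        """
        if not self.timed:
            return math.nan
        return self.tokens[-1].offset - self.tokens[0].onset


@dataclass
class BirdCorpus:
    """One individual's annotated songs plus its metadata.

    ``nucleus_volumes`` maps nucleus name (``HVC``, ``RA``, ``X``) to volume
    in mm^3; ``body_mass`` is in grams.  Both are optional covariates used
    only by the regression stage.
    """

    bird_id: str
    sex: str
    treatment: str
    songs: tuple[Song, ...]
    body_mass: float | None = None
    nucleus_volumes: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sex = _normalize_sex(self.sex)
        self.treatment = _normalize_treatment(self.treatment)
        self.songs = tuple(self.songs)

    def __len__(self) -> int:
        return len(self.songs)

    @property
    def n_tokens(self) -> int:
        return sum(len(s) for s in self.songs)

    @property
    def syllable_types(self) -> set[str]:
        return {label for song in self.songs for label in song.labels}

    def truncated(self, n_songs: int = 30) -> "BirdCorpus":
        """The first ``n_songs`` songs in recording order (the analysis window)."""
        return BirdCorpus(
            bird_id=self.bird_id,
            sex=self.sex,
            treatment=self.treatment,
            songs=self.songs[:n_songs],
            body_mass=self.body_mass,
            nucleus_volumes=dict(self.nucleus_volumes),
        )


#: canonical column order of the per-bird metrics table (eight diversity
#: metrics followed by the two network metrics)
METRIC_COLUMNS = (
    "syllable_type_repertoire",
    "song_type_repertoire",
    "syllables_per_song",
    "syllable_types_per_song",
    "syllable_types_per_second",
    "syllables_per_second",
    "svi",
    "levenshtein_distance",
    "network_path_length",
    "network_density",
)

DIVERSITY_COLUMNS = METRIC_COLUMNS[:8]
NETWORK_COLUMNS = METRIC_COLUMNS[8:]


@dataclass
class MetricsRecord:
    """Per-bird row of the metrics table: eight diversity metrics plus the
    two transition-network metrics (``nan`` when the bird's network was
    excluded or rates could not be computed)."""

    bird_id: str
    sex: str
    treatment: str
    syllable_type_repertoire: int
    song_type_repertoire: int
    syllables_per_song: float
    syllable_types_per_song: float
    syllable_types_per_second: float
    syllables_per_second: float
    svi: float
    levenshtein_distance: float
    network_path_length: float = math.nan
    network_density: float = math.nan

    def as_dict(self) -> dict[str, object]:
        d: dict[str, object] = {
            "bird_id": self.bird_id,
            "sex": self.sex,
            "treatment": self.treatment,
        }
        for col in METRIC_COLUMNS:
            d[col] = getattr(self, col)
        return d
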