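"""Synthetic canary-song corpora with the structure the analysis assumes.

Canary song is phrase-structured: a song is a sequence of phrases, each
phrase one syllable type repeated several times.  The generator works at
that level: phrase types follow a per-bird first-order Markov chain whose
transition matrix is interpolated between a uniform choice over the other
types (``stereotypy = 0``, maximally flexible syntax) and a fixed cyclic
permutation of the repertoire (``stereotypy = 1``, one rigid syllable
order).  Repertoire size and stereotypy are therefore independently
controllable — exactly the two axes on which steroid-induced male and
female song differ (males: large repertoires, near-fixed transition order;
females: small repertoires, many repeats, flexible transitions) — while
phrase counts and repeat counts are balanced so both sexes produce songs of
the same length at the same syllable rate.

Default parameter sets encode the study conditions: 15 males and 13 females
in two steroid treatments (T, T+E2), 30 songs per bird, male repertoires
around 15-16 types versus 6 in females, and around 69 syllables per song in
both sexes.

A second generator emits a per-bird metrics table directly (normal draws
around sex-specific means with a shared within-bird latent factor) so the
statistics stages can be exercised without running the corpus pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .types import BirdCorpus, Song, SyllableToken

_SEED_MOD = 2**31 - 1


@dataclass(frozen=True)
class CountDistribution:
    """Distribution over positive counts: ``fixed`` at round(mean), or
    ``1 + Poisson(mean - 1)`` (``shifted_poisson``, the default)."""

    mean: float
    kind: str = "shifted_poisson"

    def __post_init__(self) -> None:
        if self.mean < 1:
            raise ValueError("count distribution mean must be >= 1")
        if self.kind not in ("fixed", "shifted_poisson"):
            raise ValueError(f"unknown count distribution kind: {self.kind!r}")

    def sample(self, rng: np.random.Generator, size: int | None = None):
        if self.kind == "fixed":
            k = int(round(self.mean))
            return k if size is None else np.full(size, k, dtype=int)
        return 1 + rng.poisson(self.mean - 1, size=size)


@dataclass(frozen=True)
class SynthParams:
    """Generative parameters for one sex/treatment group.

    ``stereotypy`` in [0, 1] sets how concentrated phrase-to-phrase
    transitions are (0 = uniform over other types, 1 = fixed cycle).
    ``phrase_jitter_sd`` and ``repertoire_jitter_sd`` scale per-bird
    multiplicative jitters on the phrase-count mean and the repertoire size,
    giving the individual variability real corpora show.  Times are
    synthesized from ``syllable_duration`` and ``gap`` (seconds).
    """

    repertoire_size: int
    phrase_count_distribution: CountDistribution
    repeat_distribution: CountDistribution
    stereotypy: float
    syllable_duration: float = 0.08
    gap: float = 0.03
    songs_per_bird: int = 30
    phrase_jitter_sd: float = 0.08
    repertoire_jitter_sd: float = 0.12
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.repertoire_size < 1:
            raise ValueError("repertoire_size must be >= 1")
        if not 0.0 <= self.stereotypy <= 1.0:
            raise ValueError("stereotypy must be in [0, 1]")
        if self.songs_per_bird < 2:
            raise ValueError("songs_per_bird must be >= 2")


def male_default_params() -> SynthParams:
    """Large repertoire, long phrase sequences, near-fixed transition order."""
    return SynthParams(
        repertoire_size=16,
        phrase_count_distribution=CountDistribution(17.0),
        repeat_distribution=CountDistribution(4.0),
        stereotypy=0.95,
    )


def female_default_params() -> SynthParams:
    """Small repertoire, few phrases with many repeats, flexible transitions.

    The repeat mean is set so the expected syllables per song (phrases x
    repeats = 7 x 68/7) equals the male product of 17 x 4: song length and
    syllable rate are matched between the sexes by construction.
    """
    return SynthParams(
        repertoire_size=6,
        phrase_count_distribution=CountDistribution(7.0),
        repeat_distribution=CountDistribution(68.0 / 7.0),
        stereotypy=0.15,
    )


def _transition_matrix(perm: np.ndarray, stereotypy: float) -> np.ndarray:
    """Interpolate between uniform-over-others and the cycle ``i -> perm[i]``."""
    r = len(perm)
    if r == 1:
        return np.ones((1, 1))
    uniform = (np.ones((r, r)) - np.eye(r)) / (r - 1)
    cycle = np.zeros((r, r))
    cycle[np.arange(r), perm] = 1.0
    return stereotypy * cycle + (1.0 - stereotypy) * uniform


def generate_bird_corpus(
    params: SynthParams,
    bird_id: str,
    sex: str,
    treatment: str,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> BirdCorpus:
    """One bird's corpus, deterministic given the seed.

    The bird gets its own repertoire labels, its own cyclic permutation
    (the stereotyped order) and its own phrase-count jitter; each song is
    phrase types walked from the Markov chain, each expanded into repeats,
    with onset/offset times laid down from syllable duration and gap.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed if seed is None else seed)
    r = max(2, int(round(params.repertoire_size * rng.normal(1.0, params.repertoire_jitter_sd))))
    labels = np.array([f"t{i + 1:02d}" for i in range(r)])
    # a single R-cycle: visit order is a random shuffle closed into a ring
    order = rng.permutation(r)
    perm = np.empty(r, dtype=int)
    perm[order] = np.roll(order, -1)
    trans = _transition_matrix(perm, params.stereotypy)
    # birds with stereotyped syntax also open songs with a preferred phrase
    opener = int(rng.integers(r))
    jitter = max(0.2, rng.normal(1.0, params.phrase_jitter_sd))
    phrase_dist = replace(
        params.phrase_count_distribution,
        mean=max(1.0, params.phrase_count_distribution.mean * jitter),
    )

    songs = []
    t = 0.0
    for _ in range(params.songs_per_bird):
        n_phrases = int(phrase_dist.sample(rng))
        state = opener if rng.random() < params.stereotypy else int(rng.integers(r))
        tokens: list[SyllableToken] = []
        for p in range(n_phrases):
            if p > 0:
                state = int(rng.choice(r, p=trans[state]))
            n_rep = int(params.repeat_distribution.sample(rng))
            for _ in range(n_rep):
                onset = round(t, 3)
                offset = round(t + params.syllable_duration, 3)
                tokens.append(SyllableToken(str(labels[state]), onset, offset))
                t = offset + params.gap
        songs.append(Song(tuple(tokens)))
        t += 1.0  # inter-song silence, comfortably above the 0.4 s bound
    return BirdCorpus(bird_id, sex, treatment, tuple(songs))


#: sex-specific covariate distributions: (mean, sd) of nucleus volumes (mm^3)
#: and body mass (g); males have larger vocal control nuclei
COVARIATE_MEANS = {
    "male": {"hvc_volume": (0.60, 0.06), "ra_volume": (0.30, 0.03), "x_volume": (1.10, 0.10), "body_mass": (21.0, 1.3)},
    "female": {"hvc_volume": (0.33, 0.05), "ra_volume": (0.17, 0.02), "x_volume": (0.62, 0.07), "body_mass": (21.0, 1.3)},
}


def generate_study(
    male_params: SynthParams | None = None,
    female_params: SynthParams | None = None,
    n_male: int = 15,
    n_female: int = 13,
    treatments: Sequence[str] = ("T", "T+E2"),
    seed: int = 0,
    with_covariates: bool = True,
) -> list[BirdCorpus]:
    """A full study: per-bird corpora with sexes, alternating treatments.

    Treatment is a null factor — both treatment groups share their sex's
    parameter set, mirroring a design where the hormone contrast moved none
    of the syntax metrics.  Per-bird seeds derive from the study seed, so
    the whole study is reproducible from one integer.
    """
    male_params = male_params or male_default_params()
    female_params = female_params or female_default_params()
    master = np.random.default_rng(seed)
    corpora: list[BirdCorpus] = []
    groups = [("male", "M", n_male, male_params), ("female", "F", n_female, female_params)]
    for sex, prefix, n, params in groups:
        for i in range(n):
            bird_seed = int(master.integers(_SEED_MOD))
            treatment = treatments[i % len(treatments)]
            corpus = generate_bird_corpus(
                params, f"{prefix}{i + 1:02d}", sex, treatment, seed=bird_seed
            )
            if with_covariates:
                cov_rng = np.random.default_rng(bird_seed + 1)
                dists = COVARIATE_MEANS[sex]
                corpus.nucleus_volumes = {
                    "HVC": max(0.01, cov_rng.normal(*dists["hvc_volume"])),
                    "RA": max(0.01, cov_rng.normal(*dists["ra_volume"])),
                    "X": max(0.01, cov_rng.normal(*dists["x_volume"])),
                }
                corpus.body_mass = max(10.0, cov_rng.normal(*dists["body_mass"]))
            corpora.append(corpus)
    return corpora


#: per-sex (mean, sd, latent loading in sd units) for the direct metrics-table
#: generator; the shared latent factor makes repertoire-linked metrics
#: correlate within sex the way real per-bird tables do
METRIC_TABLE_MEANS = {
    "male": {
        "syllable_type_repertoire": (20.0, 3.0, 0.8),
        "song_type_repertoire": (12.0, 3.0, 0.6),
        "syllables_per_song": (69.0, 8.0, 0.0),
        "syllable_types_per_song": (15.1, 2.5, 0.8),
        "syllable_types_per_second": (2.0, 0.35, 0.6),
        "syllables_per_second": (9.0, 1.0, 0.0),
        "svi": (0.24, 0.05, 0.5),
        "levenshtein_distance": (30.0, 6.0, 0.4),
        "network_path_length": (2.8, 0.5, 0.7),
        "network_density": (0.35, 0.08, -0.5),
    },
    "female": {
        "syllable_type_repertoire": (7.0, 1.5, 0.8),
        "song_type_repertoire": (4.0, 1.5, 0.6),
        "syllables_per_song": (69.0, 8.0, 0.0),
        "syllable_types_per_song": (5.7, 1.2, 0.8),
        "syllable_types_per_second": (0.8, 0.2, 0.6),
        "syllables_per_second": (9.0, 1.0, 0.0),
        "svi": (0.09, 0.03, 0.5),
        "levenshtein_distance": (20.0, 6.0, 0.4),
        "network_path_length": (1.4, 0.25, 0.7),
        "network_density": (0.75, 0.10, -0.5),
    },
}

_METRIC_BOUNDS = {
    "svi": (0.01, 1.0),
    "network_density": (0.0, 1.0),
    "network_path_length": (1.0, None),
    "syllable_type_repertoire": (1.0, None),
    "song_type_repertoire": (1.0, None),
    "syllables_per_song": (1.0, None),
    "syllable_types_per_song": (1.0, None),
    "syllable_types_per_second": (0.01, None),
    "syllables_per_second": (0.01, None),
    "levenshtein_distance": (0.0, None),
}


def generate_metrics_table(
    n_male: int = 15,
    n_female: int = 13,
    treatments: Sequence[str] = ("T", "T+E2"),
    seed: int = 0,
    group_means: dict | None = None,
):
    """A per-bird metrics table drawn directly (synthetic stand-in for a
    deposited individual-values dataset), bypassing the corpus stages.

    Columns: bird_id, sex, treatment, the ten metrics, nucleus volumes and
    body mass.  Counts are rounded to integers; bounded metrics are clipped
    to their valid ranges.
    """
    import pandas as pd

    means = group_means or METRIC_TABLE_MEANS
    rng = np.random.default_rng(seed)
    rows = []
    for sex, prefix, n in (("male", "M", n_male), ("female", "F", n_female)):
        for i in range(n):
            latent = rng.normal()
            row: dict[str, object] = {
                "bird_id": f"{prefix}{i + 1:02d}",
                "sex": sex,
                "treatment": treatments[i % len(treatments)],
            }
            for metric, (mu, sd, load) in means[sex].items():
                val = mu + load * sd * latent + np.sqrt(max(0.0, 1 - load**2)) * sd * rng.normal()
                lo, hi = _METRIC_BOUNDS.get(metric, (None, None))
                if lo is not None:
                    val = max(lo, val)
                if hi is not None:
                    val = min(hi, val)
                if metric.endswith("repertoire"):
                    val = int(round(val))
                row[metric] = val
            dists = COVARIATE_MEANS[sex]
            row["hvc_volume"] = max(0.01, rng.normal(*dists["hvc_volume"]))
            row["ra_volume"] = max(0.01, rng.normal(*dists["ra_volume"]))
            row["x_volume"] = max(0.01, rng.normal(*dists["x_volume"]))
            row["body_mass"] = max(10.0, rng.normal(*dists["body_mass"]))
            rows.append(row)
    return pd.DataFrame(rows)


def params_from_config(path: str | Path) -> dict:
    """Load study configuration from a YAML key-value file.

    Recognized keys: ``seed``, ``n_male``, ``n_female``, ``treatments`` and
    per-sex blocks ``male``/``female`` whose entries override the default
    :class:`SynthParams` fields (count distributions given as a mean, or a
    ``{mean, kind}`` mapping).
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}

    def build(defaults: SynthParams, override: dict | None) -> SynthParams:
        if not override:
            return defaults
        kwargs = {}
        for key, value in override.items():
            if key in ("phrase_count_distribution", "repeat_distribution"):
                if isinstance(value, dict):
                    kwargs[key] = CountDistribution(**value)
                else:
                    kwargs[key] = CountDistribution(float(value))
            else:
                kwargs[key] = value
        return replace(defaults, **kwargs)

    return {
        "male_params": build(male_default_params(), raw.get("male")),
        "female_params": build(female_default_params(), raw.get("female")),
        "n_male": int(raw.get("n_male", 15)),
        "n_female": int(raw.get("n_female", 13)),
        "treatments": tuple(raw.get("treatments", ("T", "T+E2"))),
        "seed": int(raw.get("seed", 0)),
    }
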