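"""Song and syllable diversity metrics.

Eight variables capture diversity at complementary levels, per bird over its
analyzed songs (conventionally the first 30):

* **syllable-type repertoire** — distinct syllable labels across all songs;
* **song-type repertoire** — distinct song types, where a song type is by
  default the song's phrase sequence (syllable labels with consecutive
  repeats collapsed, the natural unit for phrase-structured song); an
  exact-sequence rule is available;
* **syllables per song**, **syllable types per song** — per-song counts,
  averaged;
* **syllable types per second**, **syllables per second** — per-song rates
  over the song duration (last offset minus first onset), averaged;
* **SVI**, the syllable versatility index — per-song ratio of distinct types
  to total syllables, in (0, 1], averaged;
* **Levenshtein distance** — token-level edit distance between the syllable
  sequences of successive songs (pairs 1-2, 2-3, ...), averaged; an
  all-pairs mode and normalization by the longer sequence are available.

Edit operations count whole syllable labels, not characters: two labels are
either identical or maximally different.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .types import BirdCorpus, InsufficientDataError, MetricsRecord, Song, ValidationError

__all__ = [
    "levenshtein",
    "collapse_repeats",
    "song_metrics",
    "bird_metrics",
    "SongMetrics",
]


def levenshtein(a: Sequence[str], b: Sequence[str]) -> int:
    """Minimum number of single-token insertions, deletions and
    substitutions converting sequence ``a`` into ``b``.

    Dynamic programming over one row at a time; the left-to-right dependency
    is resolved with a prefix-minimum, so each row is a vectorized update.
    """
    if len(a) < len(b):  # iterate over the longer, keep rows short
        a, b = b, a
    n = len(b)
    if n == 0:
        return len(a)
    codes = {lab: i for i, lab in enumerate(dict.fromkeys(itertools.chain(a, b)))}
    av = np.fromiter((codes[x] for x in a), dtype=np.int64, count=len(a))
    bv = np.fromiter((codes[x] for x in b), dtype=np.int64, count=n)
    idx = np.arange(n + 1)
    prev = idx.astype(np.int64).copy()
    cand = np.empty(n + 1, dtype=np.int64)
    for x in av:
        cand[0] = prev[0] + 1
        np.minimum(prev[:-1] + (bv != x), prev[1:] + 1, out=cand[1:])
        # cur[j] = min(cand[j], cur[j-1] + 1)  via prefix-min of cand[j] - j
        prev = np.minimum.accumulate(cand - idx) + idx
        cand = np.empty(n + 1, dtype=np.int64)
    return int(prev[-1])


def collapse_repeats(labels: Sequence[str]) -> tuple[str, ...]:
    """Collapse runs of consecutive identical labels to one (phrase sequence)."""
    return tuple(lab for lab, _ in itertools.groupby(labels))


@dataclass(frozen=True)
class SongMetrics:
    """Per-song values entering the bird-level averages."""

    n_syllables: int
    n_types: int
    svi: float
    types_per_second: float
    syllables_per_second: float


def song_metrics(song: Song) -> SongMetrics:
    """Count, type count, SVI and rates for one song.

    Rates are ``nan`` for untimed songs.  A timed multi-token song of zero
    duration is rejected.
    """
    n = len(song)
    if n == 0:
        raise ValidationError("song has no syllables")
    k = len(set(song.labels))
    dur = song.duration
    if math.isnan(dur):
        rate_t = rate_s = math.nan
    elif dur <= 0:
        if n > 1:
            raise ValidationError("multi-syllable song with zero duration")
        rate_t = rate_s = math.nan
    else:
        rate_t = k / dur
        rate_s = n / dur
    return SongMetrics(n, k, k / n, rate_t, rate_s)


def _song_type_key(song: Song, rule: str) -> tuple[str, ...]:
    if rule == "collapsed":
        return collapse_repeats(song.labels)
    if rule == "exact":
        return song.labels
    raise ValueError(f"unknown song-type rule: {rule!r}")


def bird_metrics(
    corpus: BirdCorpus,
    song_type_rule: str = "collapsed",
    levenshtein_mode: str = "successive",
    normalize_levenshtein: bool = False,
) -> MetricsRecord:
    """The eight diversity metrics for one bird.

    Per-song values are averaged over songs; repertoires are counted over the
    pooled corpus.  ``levenshtein_mode`` is ``"successive"`` (mean over
    consecutive song pairs, the default reading of sequence variation between
    successive songs) or ``"all_pairs"``.  With fewer than two songs the
    Levenshtein mean is undefined and reported as ``nan``; the other metrics
    are still returned.
    """
    if not corpus.songs:
        raise InsufficientDataError(f"bird {corpus.bird_id}: corpus has no songs")
    per_song = [song_metrics(s) for s in corpus.songs]

    seqs = [s.labels for s in corpus.songs]
    if levenshtein_mode == "successive":
        pairs = list(zip(seqs, seqs[1:]))
    elif levenshtein_mode == "all_pairs":
        pairs = list(itertools.combinations(seqs, 2))
    else:
        raise ValueError(f"unknown levenshtein mode: {levenshtein_mode!r}")
    dists = []
    for x, y in pairs:
        d = levenshtein(x, y)
        if normalize_levenshtein:
            m = max(len(x), len(y))
            d = d / m if m else 0.0
        dists.append(d)
    lev_mean = float(np.mean(dists)) if dists else math.nan

    return MetricsRecord(
        bird_id=corpus.bird_id,
        sex=corpus.sex,
        treatment=corpus.treatment,
        syllable_type_repertoire=len(corpus.syllable_types),
        song_type_repertoire=len({_song_type_key(s, song_type_rule) for s in corpus.songs}),
        syllables_per_song=float(np.mean([m.n_syllables for m in per_song])),
        syllable_types_per_song=float(np.mean([m.n_types for m in per_song])),
        syllable_types_per_second=float(np.mean([m.types_per_second for m in per_song])),
        syllables_per_second=float(np.mean([m.syllables_per_second for m in per_song])),
        svi=float(np.mean([m.svi for m in per_song])),
        levenshtein_distance=lev_mean,
    )
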