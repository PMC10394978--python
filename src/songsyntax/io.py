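"""Reading and writing song annotations and metric tables.

Two annotation inputs are supported:

* PRAAT TextGrid interval tiers (one file per bird/recording), where each
  non-empty labelled interval is one syllable and empty intervals are silence;
* a plain tab-separated sequence table with columns ``bird_id``, ``sex``,
  ``treatment``, ``song_index``, ``syllable``, ``onset_s``, ``offset_s``
  (times optional; ``song_index`` optional when times are present, in which
  case songs are split at silent gaps >= 0.4 s, the silence bound of the
  song definition).

The per-bird metrics output is a CSV with one row per bird and the eight
diversity metrics plus the two network metrics as columns.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from . import textgrid
from .types import (
    METRIC_COLUMNS,
    BirdCorpus,
    MetricsRecord,
    ParseError,
    Song,
    SyllableToken,
    ValidationError,
)

#: minimum silent gap (s) separating two songs
SONG_GAP_S = 0.4
#: minimum duration (s) for a vocalization to count as a song
MIN_SONG_DURATION_S = 1.0

SEQUENCE_COLUMNS = ("bird_id", "sex", "treatment", "song_index", "syllable", "onset_s", "offset_s")


def parse_textgrid(path: str | Path, tier_name: str) -> list[SyllableToken]:
    """Syllable tokens from the named interval tier of a TextGrid file.

    Empty-label intervals (silence) are dropped; labelled intervals must be
    time-ordered and non-overlapping.
    """
    tier = textgrid.get_interval_tier(path, tier_name)
    tokens: list[SyllableToken] = []
    for iv in tier.intervals:
        label = iv.text.strip()
        if not label:
            continue
        tok = SyllableToken(label=label, onset=round(iv.xmin, 3), offset=round(iv.xmax, 3))
        if tokens and tok.onset < tokens[-1].offset - 1e-6:
            raise ValidationError(
                f"{path}: labelled intervals overlap near t={tok.onset:.3f} s"
            )
        tokens.append(tok)
    return tokens


def split_songs(
    tokens: Sequence[SyllableToken],
    gap_s: float = SONG_GAP_S,
    min_duration_s: float | None = MIN_SONG_DURATION_S,
) -> list[Song]:
    """Segment a timed token stream into songs at silent gaps >= ``gap_s``.

    Songs shorter than ``min_duration_s`` are discarded (pass ``None`` to keep
    everything).
    """
    songs: list[Song] = []
    run: list[SyllableToken] = []
    for tok in tokens:
        if not tok.timed:
            raise ValidationError("song splitting requires onset/offset times")
        if run and tok.onset - run[-1].offset >= gap_s - 1e-9:
            songs.append(Song(tuple(run)))
            run = []
        run.append(tok)
    if run:
        songs.append(Song(tuple(run)))
    if min_duration_s is not None:
        songs = [s for s in songs if s.duration >= min_duration_s - 1e-9]
    return songs


def _songs_from_group(g: pd.DataFrame, timed: bool, split: bool) -> list[Song]:
    def tok(row) -> SyllableToken:
        if timed:
            return SyllableToken(str(row.syllable), round(float(row.onset_s), 3), round(float(row.offset_s), 3))
        return SyllableToken(str(row.syllable))

    if "song_index" in g.columns and g["song_index"].notna().all():
        songs = []
        for _, sg in g.groupby("song_index", sort=True):
            songs.append(Song(tuple(tok(r) for r in sg.itertuples())))
        return songs
    if not timed:
        raise ValidationError("rows without song_index need onset_s/offset_s for splitting")
    tokens = [tok(r) for r in g.itertuples()]
    if split:
        return split_songs(tokens, min_duration_s=None)
    return [Song(tuple(tokens))]


def parse_sequence_table(path: str | Path) -> list[BirdCorpus]:
    """Read a sequence-table TSV into one corpus per bird.

    Rows are grouped by ``bird_id`` then ``song_index``; when ``song_index``
    is absent, songs are split wherever the silent gap between consecutive
    tokens reaches 0.4 s.  Onsets must be non-decreasing within a song.
    """
    df = pd.read_csv(path, sep="\t", dtype={"bird_id": str, "syllable": str})
    missing = {"bird_id", "sex", "treatment", "syllable"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing required columns {sorted(missing)}")
    timed = {"onset_s", "offset_s"}.issubset(df.columns) and df[["onset_s", "offset_s"]].notna().all().all()
    corpora: list[BirdCorpus] = []
    if df.empty:
        return corpora
    for bird_id, g in df.groupby("bird_id", sort=True):
        sex = g["sex"].iloc[0]
        trt = g["treatment"].iloc[0]
        if timed:
            ons = g.groupby("song_index")["onset_s"].diff() if "song_index" in g else g["onset_s"].diff()
            if (ons.dropna() < -1e-9).any():
                raise ValidationError(f"bird {bird_id}: non-monotone onsets within a song")
        songs = _songs_from_group(g, timed, split=True)
        corpora.append(BirdCorpus(str(bird_id), str(sex), str(trt), tuple(songs)))
    return corpora


def write_sequence_table(corpora: Iterable[BirdCorpus], path: str | Path) -> None:
    """Write corpora to the sequence-table TSV format (times at ms precision)."""
    rows = []
    for c in corpora:
        for i, song in enumerate(c.songs, start=1):
            for tok in song.tokens:
                rows.append(
                    {
                        "bird_id": c.bird_id,
                        "sex": c.sex,
                        "treatment": c.treatment,
                        "song_index": i,
                        "syllable": tok.label,
                        "onset_s": None if tok.onset is None else round(tok.onset, 3),
                        "offset_s": None if tok.offset is None else round(tok.offset, 3),
                    }
                )
    pd.DataFrame(rows, columns=list(SEQUENCE_COLUMNS)).to_csv(path, sep="\t", index=False)


def metrics_frame(records: Iterable[MetricsRecord]) -> pd.DataFrame:
    """Assemble per-bird records into the canonical metrics table."""
    df = pd.DataFrame([r.as_dict() for r in records])
    if df.empty:
        df = pd.DataFrame(columns=["bird_id", "sex", "treatment", *METRIC_COLUMNS])
    return df


def write_metrics_csv(records: Iterable[MetricsRecord], path: str | Path) -> pd.DataFrame:
    df = metrics_frame(records)
    df.to_csv(path, index=False, float_format="%.6g")
    return df


def read_metrics_csv(path: str | Path) -> pd.DataFrame:
    """Read a per-bird metrics table (the package's own output or any
    equivalently shaped table, e.g. a supplementary dataset).

    Requires ``bird_id``, ``sex``, ``treatment`` and at least one metric
    column; extra covariate columns (nucleus volumes, body mass) pass through.
    """
    df = pd.read_csv(path, dtype={"bird_id": str})
    required = {"bird_id", "sex", "treatment"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: metrics table needs columns {sorted(required)}")
    present = [c for c in METRIC_COLUMNS if c in df.columns]
    if not present:
        raise ParseError(f"{path}: no metric columns found (expected some of {METRIC_COLUMNS})")
    return df
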