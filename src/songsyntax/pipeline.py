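"""End-to-end orchestration: corpora -> metrics -> networks -> statistics.

The pipeline accepts three input kinds:

* ``textgrid_dir`` — a directory of PRAAT TextGrid files plus a
  ``metadata.tsv`` (columns ``bird_id``, ``sex``, ``treatment``, ``file``
  and optionally ``tier``, nucleus volumes, body mass);
* ``sequence_table`` — the tabular annotation format of :mod:`songsyntax.io`;
* ``metrics_table`` — an already-computed per-bird metrics CSV (e.g. a
  deposited individual-values dataset), which skips the corpus stages and
  runs the statistics only.

Control-treatment birds are excluded from the statistics (the sex contrast
is defined within the steroid-treated groups); birds with small transition
networks lose their network metrics.  Every exclusion is logged with its
reason, because exclusions drive the degrees of freedom of the ANOVA table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from . import io as sio
from .diversity import bird_metrics
from .network import DEFAULT_EXCLUSION_THRESHOLD, export_graphml, network_metrics_for_study
from .stats import (
    NUCLEUS_PREDICTORS,
    anova_table,
    diversity_variables,
    pca_unrotated,
    pearson_correlation,
    regressions_by_sex,
)
from .types import BirdCorpus, METRIC_COLUMNS, SongSyntaxError

logger = logging.getLogger(__name__)

INPUT_KINDS = ("textgrid_dir", "sequence_table", "metrics_table")

_COVARIATE_RENAME = {"HVC": "hvc_volume", "RA": "ra_volume", "X": "x_volume"}


@dataclass
class RunConfig:
    """Configuration of one full analysis run."""

    input_path: str | Path
    input_kind: str
    output_dir: str | Path
    tier_name: str = "syllables"
    songs_per_bird: int = 30
    song_type_rule: str = "collapsed"
    levenshtein_mode: str = "successive"
    normalize_levenshtein: bool = False
    network_exclusion_threshold: int = DEFAULT_EXCLUSION_THRESHOLD
    include_network_in_pca: bool = False
    n_components: int = 3
    export_networks: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_kind not in INPUT_KINDS:
            raise ValueError(f"input_kind must be one of {INPUT_KINDS}")
        if self.network_exclusion_threshold < 0:
            raise ValueError("network exclusion threshold must be >= 0")


@dataclass
class RunResult:
    """Tables produced by a run (also written as CSV to the output dir)."""

    metrics: pd.DataFrame
    anova: pd.DataFrame | None = None
    pca_summary: pd.DataFrame | None = None
    pca_loadings: pd.DataFrame | None = None
    pca_scores: pd.DataFrame | None = None
    regression: pd.DataFrame | None = None
    correlations: pd.DataFrame | None = None
    exclusions: list[str] = field(default_factory=list)
    output_dir: Path | None = None


def _load_textgrid_dir(path: Path, default_tier: str) -> list[BirdCorpus]:
    meta_path = path / "metadata.tsv"
    if not meta_path.exists():
        raise SongSyntaxError(f"{path}: textgrid_dir input needs a metadata.tsv")
    meta = pd.read_csv(meta_path, sep="\t", dtype={"bird_id": str})
    corpora = []
    for row in meta.itertuples():
        tier = getattr(row, "tier", None) or default_tier
        tokens = sio.parse_textgrid(path / str(row.file), str(tier))
        songs = sio.split_songs(tokens)
        volumes = {
            k: float(getattr(row, v))
            for k, v in _COVARIATE_RENAME.items()
            if hasattr(row, v) and not pd.isna(getattr(row, v))
        }
        mass = getattr(row, "body_mass", None)
        corpora.append(
            BirdCorpus(
                str(row.bird_id),
                str(row.sex),
                str(row.treatment),
                tuple(songs),
                body_mass=None if mass is None or pd.isna(mass) else float(mass),
                nucleus_volumes=volumes,
            )
        )
    return corpora


def compute_metrics_table(corpora: Iterable[BirdCorpus], config: RunConfig) -> tuple[pd.DataFrame, list[str]]:
    """Diversity + network metrics for every corpus, with exclusion log lines."""
    log: list[str] = []
    corpora = [c.truncated(config.songs_per_bird) for c in corpora]
    for c in corpora:
        if len(c) < config.songs_per_bird:
            log.append(
                f"flag: bird {c.bird_id} has only {len(c)} songs "
                f"(< {config.songs_per_bird}); metrics computed on what is available"
            )
    records = [
        bird_metrics(
            c,
            song_type_rule=config.song_type_rule,
            levenshtein_mode=config.levenshtein_mode,
            normalize_levenshtein=config.normalize_levenshtein,
        )
        for c in corpora
    ]
    net, excluded = network_metrics_for_study(corpora, config.network_exclusion_threshold)
    for bird_id in excluded:
        log.append(
            f"exclude (network metrics only): bird {bird_id} has a transition network "
            f"with <= {config.network_exclusion_threshold} syllable types"
        )
    df = sio.metrics_frame(records).merge(
        net.drop(columns=["n_nodes"]), on="bird_id", how="left"
    )
    # bird_metrics leaves the network columns nan; the merge supplies them
    df["network_path_length"] = df["network_path_length_y"]
    df["network_density"] = df["network_density_y"]
    df = df.drop(columns=[c for c in df.columns if c.endswith(("_x", "_y"))])
    cov_rows = {
        c.bird_id: {
            **{_COVARIATE_RENAME[k]: v for k, v in c.nucleus_volumes.items() if k in _COVARIATE_RENAME},
            **({"body_mass": c.body_mass} if c.body_mass is not None else {}),
        }
        for c in corpora
    }
    cov = pd.DataFrame.from_dict(cov_rows, orient="index").rename_axis("bird_id").reset_index()
    if not cov.empty and cov.shape[1] > 1:
        df = df.merge(cov, on="bird_id", how="left")
    return df, log


def run_statistics(table: pd.DataFrame, config: RunConfig) -> RunResult:
    """Group statistics on a per-bird metrics table (any input kind)."""
    log: list[str] = []
    stats_table = table[table["treatment"] != "control"].copy()
    for bird_id in table.loc[table["treatment"] == "control", "bird_id"]:
        log.append(f"exclude (all statistics): bird {bird_id} is in the control group")

    result = RunResult(metrics=table, exclusions=log)
    sex_counts = stats_table["sex"].value_counts()
    if len(stats_table) == 0 or (sex_counts < 2).any() or len(sex_counts) < 2:
        logger.warning("fewer than 2 birds per sex after exclusions; statistics skipped")
        log.append("warning: fewer than 2 birds per sex after exclusions; statistics skipped")
        return result

    metrics_present = [m for m in METRIC_COLUMNS if m in stats_table.columns]
    result.anova = anova_table(stats_table, metrics=metrics_present)

    pca_vars = diversity_variables(stats_table)
    if config.include_network_in_pca:
        pca_vars = metrics_present
    if len(pca_vars) >= 2:
        pca = pca_unrotated(stats_table, variables=pca_vars)
        for idx in pca.dropped_rows:
            log.append(
                f"exclude (PCA/regression): bird {stats_table.loc[idx, 'bird_id']} "
                f"has missing values among {pca_vars}"
            )
        k = min(config.n_components, len(pca.eigenvalues))
        result.pca_summary = pd.DataFrame(
            {
                "component": [f"PC{i + 1}" for i in range(len(pca.eigenvalues))],
                "eigenvalue": pca.eigenvalues,
                "proportion_explained": pca.proportion_explained,
                "cumulative_proportion": pca.proportion_explained.cumsum(),
            }
        )
        result.pca_loadings = pca.loadings
        result.pca_scores = pca.scores.join(
            stats_table[["bird_id", "sex", "treatment"]]
        )
        predictors = [p for p in NUCLEUS_PREDICTORS if p in stats_table.columns]
        kept = stats_table.loc[pca.scores.index]
        enough_rows = (
            not kept.empty
            and kept.groupby("sex").size().min() >= len(NUCLEUS_PREDICTORS) + 2
        )
        if (
            len(predictors) == len(NUCLEUS_PREDICTORS)
            and stats_table[predictors].notna().all().all()
            and enough_rows
        ):
            result.regression = regressions_by_sex(
                stats_table,
                pca.scores[[f"PC{i + 1}" for i in range(k)]],
            )
        else:
            log.append(
                "note: regressions skipped (nucleus volume/body mass covariates "
                "absent or too few birds per sex)"
            )

    # repertoire vs path length, the headline syntax correlation, per sex
    corr_rows = []
    if {"syllable_type_repertoire", "network_path_length"}.issubset(stats_table.columns):
        for sex, g in stats_table.groupby("sex"):
            sub = g.dropna(subset=["network_path_length"])
            if (
                len(sub) >= 3
                and sub["syllable_type_repertoire"].nunique() > 1
                and sub["network_path_length"].nunique() > 1
            ):
                corr_rows.append(
                    {
                        "sex": sex,
                        "x": "syllable_type_repertoire",
                        "y": "network_path_length",
                        "r": pearson_correlation(
                            sub["syllable_type_repertoire"], sub["network_path_length"]
                        ),
                        "n": len(sub),
                    }
                )
    if corr_rows:
        result.correlations = pd.DataFrame(corr_rows)
    result.exclusions = log
    return result


def _write_outputs(result: RunResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.metrics.to_csv(outdir / "metrics.csv", index=False, float_format="%.6g")
    pairs = [
        ("anova.csv", result.anova, False),
        ("pca_summary.csv", result.pca_summary, False),
        ("pca_loadings.csv", result.pca_loadings, True),
        ("pca_scores.csv", result.pca_scores, False),
        ("regression.csv", result.regression, False),
        ("correlations.csv", result.correlations, False),
    ]
    for name, frame, keep_index in pairs:
        if frame is not None:
            frame.to_csv(outdir / name, index=keep_index, float_format="%.6g")
    (outdir / "exclusions.log").write_text(
        "".join(line + "\n" for line in result.exclusions)
    )
    result.output_dir = outdir


def run_full_analysis(config: RunConfig, corpora: Sequence[BirdCorpus] | None = None) -> RunResult:
    """Run the configured stages and write the output bundle.

    ``corpora`` may be passed directly (e.g. synthetic studies); otherwise
    they are loaded according to ``config.input_kind``.  With a
    ``metrics_table`` input the corpus stages are skipped entirely.
    """
    path = Path(config.input_path)
    if corpora is None and config.input_kind == "metrics_table":
        table = sio.read_metrics_csv(path)
        result = run_statistics(table, config)
        _write_outputs(result, Path(config.output_dir))
        return result

    if corpora is None:
        if config.input_kind == "textgrid_dir":
            corpora = _load_textgrid_dir(path, config.tier_name)
        else:
            corpora = sio.parse_sequence_table(path)

    table, log = compute_metrics_table(corpora, config)
    result = run_statistics(table, config)
    result.exclusions = log + result.exclusions
    outdir = Path(config.output_dir)
    _write_outputs(result, outdir)
    if config.export_networks:
        netdir = outdir / "networks"
        netdir.mkdir(parents=True, exist_ok=True)
        for c in corpora:
            export_graphml(c.truncated(config.songs_per_bird), netdir / f"{c.bird_id}.graphml")
    return result
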