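"""File readers/writers, run configuration and the end-to-end pipeline.

Canonical tabular format is TSV (UTF-8, header row, empty cell = missing).
Numeric formatting is fixed — ranks to 2 decimals, raw metric dumps to 4 —
so identical inputs produce byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from draftrank.assembly_metrics import (
    DEFAULT_CHAFF_MIN_LEN,
    Level,
    MetricSet,
    compute_metric_set,
    read_assembly,
)
from draftrank.classifier import DEFAULT_VOCAB, AxisProfile, assign_axis_classes
from draftrank.rank_engine import (
    Direction,
    Group,
    GroupWeights,
    MetricSpec,
    MetricTable,
    RankTable,
    Ties,
    build_rank_table,
    default_metric_specs,
)

logger = logging.getLogger(__name__)

CONSERVATION_COLS = ["csg1_pct", "csg2_pct", "csg3_pct", "csg4_pct"]
COMPUTE_COLS = ["running_time", "peak_memory"]


@dataclass(frozen=True)
class RunConfig:
    """All tunables of one pipeline run."""

    manifest: Path
    conservation: Path | None = None
    compute: Path | None = None
    outdir: Path = Path("draftrank_out")
    chaff_min_len: int = DEFAULT_CHAFF_MIN_LEN
    ties: Ties = Ties.COMPETITION
    metric_specs: tuple[MetricSpec, ...] = tuple(default_metric_specs())
    group_weights: GroupWeights = field(default_factory=GroupWeights)
    axis_vocab: dict = field(default_factory=lambda: dict(DEFAULT_VOCAB))
    exclude_from_computational: tuple[str, ...] = ()
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a config file; keyword overrides win over file values."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict = {}
        if "manifest" in raw:
            kwargs["manifest"] = Path(raw["manifest"])
        for key in ("conservation", "compute", "outdir"):
            if raw.get(key):
                kwargs[key] = Path(raw[key])
        if "chaff_min_len" in raw:
            kwargs["chaff_min_len"] = int(raw["chaff_min_len"])
        if "ties" in raw:
            kwargs["ties"] = Ties(raw["ties"])
        if "seed" in raw:
            kwargs["seed"] = int(raw["seed"])
        if "group_weights" in raw:
            kwargs["group_weights"] = GroupWeights(dict(raw["group_weights"]))
        if "metrics" in raw:
            kwargs["metric_specs"] = tuple(
                MetricSpec(
                    m["metric_id"],
                    Group(m["group"]),
                    Direction(m["direction"]),
                    float(m.get("weight", 1.0)),
                )
                for m in raw["metrics"]
            )
        if "exclude_from_computational" in raw:
            kwargs["exclude_from_computational"] = tuple(
                raw["exclude_from_computational"]
            )
        kwargs.update(overrides)
        return cls(**kwargs)


def load_manifest(path: str | Path) -> list[tuple[str, Level, Path]]:
    """Read an assembly manifest TSV with columns name, level, path.

    Paths are resolved relative to the manifest's directory. Duplicate
    names, unknown levels and missing FASTA files are hard errors.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"name", "level", "path"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"{path}: manifest must have columns {sorted(required)}"
        )
    out: list[tuple[str, Level, Path]] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        name = row["name"]
        if name in seen:
            raise ValueError(f"{path}: duplicate assembly name {name!r}")
        seen.add(name)
        try:
            level = Level(row["level"])
        except ValueError:
            raise ValueError(
                f"{path}: unknown level {row['level']!r} for {name!r}"
                f" (expected one of: {', '.join(l.value for l in Level)})"
            ) from None
        fasta = Path(row["path"])
        if not fasta.is_absolute():
            fasta = path.parent / fasta
        if not fasta.exists():
            raise FileNotFoundError(f"{path}: FASTA not found: {fasta}")
        out.append((name, level, fasta))
    return out


def _check_items(
    df: pd.DataFrame, manifest_names: set[str] | None, label: str
) -> None:
    if manifest_names is None:
        return
    extra = [n for n in df.index if n not in manifest_names]
    if extra:
        logger.warning("%s: items not in manifest (rows kept): %s", label, extra)


def load_tables(
    conservation_path: str | Path | None,
    compute_path: str | Path | None,
    manifest_names: Sequence[str] | None = None,
) -> tuple[pd.DataFrame | None, pd.DataFrame | None]:
    """Load the conservation and computational metric TSVs.

    Conservation percentages must lie in [0, 100]; compute values must be
    positive where present. Items absent from the manifest are kept with a
    warning.
    """
    names = set(manifest_names) if manifest_names is not None else None
    conservation = None
    if conservation_path is not None:
        conservation = pd.read_csv(
            conservation_path, sep="\t", index_col="name"
        )
        for col in CONSERVATION_COLS:
            if col not in conservation.columns:
                raise ValueError(
                    f"{conservation_path}: missing column {col!r}"
                )
            bad = conservation[
                (conservation[col] < 0) | (conservation[col] > 100)
            ]
            if len(bad):
                raise ValueError(
                    f"{conservation_path}: {col} out of [0,100] for"
                    f" {list(bad.index)}"
                )
        _check_items(conservation, names, "conservation table")
    compute = None
    if compute_path is not None:
        compute = pd.read_csv(compute_path, sep="\t", index_col="name")
        for col in COMPUTE_COLS:
            if col in compute.columns:
                bad = compute[compute[col] <= 0]
                if len(bad):
                    raise ValueError(
                        f"{compute_path}: {col} must be > 0, offending"
                        f" items {list(bad.index)}"
                    )
        if len(compute) == 0:
            logger.info("compute table empty; pipeline proceeds quality-only")
            compute = None
        else:
            _check_items(compute, names, "compute table")
    return conservation, compute


def metric_sets_to_frame(metric_sets: Sequence[MetricSet]) -> pd.DataFrame:
    """One-row-per-assembly metrics table, indexed by name."""
    rows = []
    for ms in metric_sets:
        rows.append(
            {
                "name": ms.name,
                "level": ms.level.value,
                "num_contigs_all": ms.num_contigs_all,
                "num_contigs_kept": ms.num_contigs_kept,
                "total_len_all": ms.total_len_all,
                "total_len_kept": ms.total_len_kept,
                "largest_contig": ms.largest_contig,
                "n50": ms.n50,
                "l50": ms.l50,
                "chaff_pct": ms.chaff_pct,
                "n_count": ms.n_count,
            }
        )
    return pd.DataFrame(rows).set_index("name")


def write_metrics_tsv(frame: pd.DataFrame, path: str | Path) -> None:
    out = frame.copy()
    out["chaff_pct"] = out["chaff_pct"].map(lambda v: f"{v:.4f}")
    out.to_csv(path, sep="\t")


def read_metrics_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="name")


def write_rank_outputs(
    rank_table: RankTable, prefix: Path
) -> tuple[Path, Path]:
    """Write a rank table as TSV and a mirroring JSON report.

    Metric ranks are integers (blank when missing); group and overall
    ranks print with 2 decimals.
    """
    tsv = prefix.with_suffix(".tsv")
    js = prefix.with_suffix(".json")

    df = rank_table.metric_ranks.copy()
    for col in df.columns:
        df[col] = df[col].map(
            lambda v: "" if math.isnan(v) else str(int(v))
        )
    for g in rank_table.group_ranks.columns:
        df[f"R_{g}"] = rank_table.group_ranks[g].map(
            lambda v: "" if math.isnan(v) else f"{v:.2f}"
        )
    df["R"] = rank_table.overall.map(
        lambda v: "" if math.isnan(v) else f"{v:.2f}"
    )
    df.to_csv(tsv, sep="\t")

    payload = {
        "ties": rank_table.ties.value,
        "incomplete": list(rank_table.incomplete),
        "items": {
            item: {
                "metric_ranks": {
                    m: (None if math.isnan(v) else v)
                    for m, v in rank_table.metric_ranks.loc[item].items()
                },
                "group_ranks": {
                    g: (None if math.isnan(v) else round(v, 4))
                    for g, v in rank_table.group_ranks.loc[item].items()
                },
                "overall": (
                    None
                    if math.isnan(rank_table.overall[item])
                    else round(float(rank_table.overall[item]), 4)
                ),
            }
            for item in rank_table.metric_ranks.index
        },
    }
    js.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return tsv, js


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """End-to-end: FASTA metrics -> merged table -> ranks -> classes.

    Writes, under ``config.outdir``: per-level metrics TSVs, per-level
    rank TSV/JSON, a classification TSV (when computational data exist),
    and a Markdown summary. Returns the paths keyed by artifact name.
    The contigs-level overall rank is the quality rank used for
    classification.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    manifest = load_manifest(config.manifest)
    conservation, compute = load_tables(
        config.conservation, config.compute, [m[0] for m in manifest]
    )
    if conservation is None:
        logger.info("no conservation table; quality ranks use g1+g2 only")

    levels = sorted({level for _, level, _ in manifest}, key=lambda l: l.value)
    rank_tables: dict[Level, RankTable] = {}
    for level in levels:
        sets = [
            compute_metric_set(
                read_assembly(fasta, name, level), config.chaff_min_len
            )
            for name, lv, fasta in manifest
            if lv is level
        ]
        frame = metric_sets_to_frame(sets)
        metrics_path = outdir / f"metrics_{level.value}.tsv"
        write_metrics_tsv(frame, metrics_path)
        outputs[f"metrics_{level.value}"] = metrics_path

        merged = frame.drop(columns=["level"]).astype(float)
        if conservation is not None:
            merged = merged.join(conservation[CONSERVATION_COLS], how="left")
        if compute is not None:
            merged = merged.join(compute, how="left")
        table = MetricTable.from_frame(merged, config.metric_specs)
        rt = build_rank_table(
            table,
            ties=config.ties,
            group_weights=config.group_weights,
            exclude_from_computational=config.exclude_from_computational,
        )
        rank_tables[level] = rt
        tsv, js = write_rank_outputs(rt, outdir / f"ranks_{level.value}")
        outputs[f"ranks_{level.value}_tsv"] = tsv
        outputs[f"ranks_{level.value}_json"] = js
        if rt.incomplete:
            logger.info(
                "%s level: items without overall rank: %s",
                level.value,
                rt.incomplete,
            )

    classes = None
    if compute is not None and Level.CONTIGS in rank_tables:
        classes = _classify(rank_tables[Level.CONTIGS], config)
        cls_path = outdir / "classes.tsv"
        classes.to_csv(cls_path, sep="\t")
        outputs["classes"] = cls_path

    summary = outdir / "summary.md"
    summary.write_text(_summary_markdown(rank_tables, classes, config))
    outputs["summary"] = summary
    return outputs


def _classify(rank_table: RankTable, config: RunConfig) -> pd.DataFrame:
    """Build the per-axis class table from a single-dataset rank table."""
    axes: dict[str, pd.Series] = {}
    if "running_time" in rank_table.metric_ranks:
        axes["time"] = rank_table.metric_ranks["running_time"]
    if "peak_memory" in rank_table.metric_ranks:
        axes["memory"] = rank_table.metric_ranks["peak_memory"]
    axes["quality"] = rank_table.overall

    rows: dict[str, dict[str, str]] = {}
    for axis, scores in axes.items():
        scores = scores.dropna()
        vocab = tuple(config.axis_vocab.get(axis, DEFAULT_VOCAB[axis]))
        k = min(len(vocab), len(scores.unique()))
        profile = AxisProfile(
            axis=axis, scores=dict(scores), label_vocab=vocab[:k]
        )
        assignment = assign_axis_classes(profile, seed=config.seed)
        for name, label in assignment.labels.items():
            rows.setdefault(name, {})[f"{axis}_class"] = label
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    df.index.name = "name"
    return df


def _summary_markdown(
    rank_tables: dict[Level, RankTable],
    classes: pd.DataFrame | None,
    config: RunConfig,
) -> str:
    lines = ["# draftrank summary", ""]
    lines.append(f"Tie convention: {config.ties.value}")
    lines.append(f"Chaff threshold: < {config.chaff_min_len} bp")
    lines.append("")
    for level, rt in sorted(rank_tables.items(), key=lambda kv: kv[0].value):
        lines.append(f"## Overall quality rank ({level.value} level)")
        lines.append("")
        lines.append("| item | R |")
        lines.append("|---|---|")
        for item in rt.overall.sort_values().index:
            v = rt.overall[item]
            lines.append(
                f"| {item} | {'-' if math.isnan(v) else f'{v:.2f}'} |"
            )
        lines.append("")
    if classes is not None:
        lines.append("## Performance classes")
        lines.append("")
        cols = list(classes.columns)
        lines.append("| item | " + " | ".join(cols) + " |")
        lines.append("|" + "---|" * (len(cols) + 1))
        for item, row in classes.iterrows():
            lines.append(
                f"| {item} | " + " | ".join(str(row[c]) for c in cols) + " |"
            )
        lines.append("")
    return "\n".join(lines)
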