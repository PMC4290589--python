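"""Synthetic assemblies and metric tables with planted ground truth.

Emulates, at toy scale, what a cohort of short-read assemblers produces on
a fungal-sized genome: per-assembly FASTA files whose contig lengths are
log-normal (heavy right tail, as in real assemblies), a controllable
fraction of chaff records (< 200 bp), and uncalled bases substituted at a
per-base rate. Cohorts plant a total quality ordering by making each
successive assembly strictly worse, in expectation, on every goodness and
problem metric, so the rank pipeline's output ordering can be asserted
against the ground truth.

What this does not emulate: read-level error profiles, genome repeat
structure, assembler-specific failure modes, or any correlation structure
between metrics beyond the planted monotone trend.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from draftrank.assembly_metrics import Assembly, Level

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class AssemblySpec:
    """Parameters for one synthetic assembly.

    Kept (non-chaff) contig lengths are log-normal with the given mean and
    sigma on the log scale, truncated at ``min_kept_len``; chaff records
    are uniform on [50, 199] bp.
    """

    name: str
    n_contigs: int = 100
    log_mean: float = 8.0
    log_sigma: float = 1.0
    chaff_fraction: float = 0.0
    n_rate: float = 0.0
    min_kept_len: int = 200
    level: Level = Level.CONTIGS

    def __post_init__(self) -> None:
        if self.n_contigs < 1:
            raise ValueError("n_contigs must be >= 1")
        if not 0.0 <= self.chaff_fraction <= 1.0:
            raise ValueError("chaff_fraction must be in [0, 1]")
        if not 0.0 <= self.n_rate <= 1.0:
            raise ValueError("n_rate must be in [0, 1]")


@dataclass(frozen=True)
class CohortSpec:
    """A planted-ordering cohort: assemblies listed best to worst.

    ``quality_step`` controls how much each successive assembly degrades:
    kept-length scale shrinks, chaff fraction and N rate grow. The planted
    ordering equals the listing order of ``names``.
    """

    names: tuple[str, ...]
    n_contigs: int = 150
    base_log_mean: float = 8.5
    log_sigma: float = 0.6
    base_chaff_fraction: float = 0.02
    base_n_rate: float = 0.001
    quality_step: float = 0.8

    def assembly_specs(self) -> list[AssemblySpec]:
        specs = []
        for i, name in enumerate(self.names):
            specs.append(
                AssemblySpec(
                    name=name,
                    n_contigs=self.n_contigs,
                    log_mean=self.base_log_mean - self.quality_step * i,
                    log_sigma=self.log_sigma,
                    chaff_fraction=min(
                        0.9, self.base_chaff_fraction + 0.08 * i
                    ),
                    n_rate=min(0.2, self.base_n_rate + 0.004 * i),
                )
            )
        return specs


def generate_assembly(spec: AssemblySpec, seed: int) -> Assembly:
    """Draw a synthetic assembly; deterministic given (spec, seed)."""
    rng = np.random.default_rng(seed)
    n_chaff = int(rng.binomial(spec.n_contigs, spec.chaff_fraction))
    n_kept = spec.n_contigs - n_chaff
    if n_kept == 0 and spec.chaff_fraction < 1.0:
        n_kept, n_chaff = 1, n_chaff - 1

    kept = rng.lognormal(spec.log_mean, spec.log_sigma, size=n_kept)
    kept = np.maximum(kept.astype(int), spec.min_kept_len)
    chaff = rng.integers(50, spec.min_kept_len, size=n_chaff)
    lengths = np.concatenate([kept, chaff]).astype(int)
    rng.shuffle(lengths)

    records = []
    for i, length in enumerate(lengths):
        seq = rng.choice(_BASES, size=int(length))
        if spec.n_rate > 0:
            mask = rng.random(int(length)) < spec.n_rate
            seq[mask] = "N"
        records.append((f"{spec.name}_contig_{i}", "".join(seq)))
    return Assembly(name=spec.name, level=spec.level, records=tuple(records))


def write_fasta(assembly: Assembly, path: str | Path, width: int = 70) -> None:
    """Write an assembly as wrapped multi-FASTA."""
    with open(path, "w") as fh:
        for rid, seq in assembly.records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def generate_cohort(
    spec: CohortSpec, seed: int
) -> tuple[list[Assembly], list[str]]:
    """Generate a cohort of assemblies plus its planted quality ordering.

    The i-th assembly uses a seed derived from (seed, i) so cohorts are
    reproducible and assemblies independent.
    """
    if len(spec.names) != len(set(spec.names)):
        raise ValueError("cohort names must be unique")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(spec.names))
    assemblies = [
        generate_assembly(a_spec, int(child.generate_state(1)[0] % 2**31))
        for a_spec, child in zip(spec.assembly_specs(), children)
    ]
    return assemblies, list(spec.names)


def conservation_for_cohort(
    spec: CohortSpec, seed: int, noise: float = 1.0
) -> dict[str, dict[str, float]]:
    """Conservation-group completeness percentages consistent with the
    planted ordering: monotone decreasing down the order plus bounded
    noise small enough (vs the 6-point step) to preserve the ordering.
    """
    rng = np.random.default_rng(seed + 7)
    table: dict[str, dict[str, float]] = {}
    for i, name in enumerate(spec.names):
        base = 95.0 - 6.0 * i
        table[name] = {
            f"csg{g}_pct": float(
                np.clip(base + rng.uniform(-noise, noise), 0.0, 100.0)
            )
            for g in range(1, 5)
        }
    return table


def compute_for_cohort(
    spec: CohortSpec, seed: int
) -> dict[str, dict[str, float]]:
    """Running time (h) and peak memory (GB) with an arbitrary ordering
    independent of quality, as computational cost does not track quality.
    """
    rng = np.random.default_rng(seed + 13)
    return {
        name: {
            "running_time": float(rng.uniform(0.5, 20.0)),
            "peak_memory": float(rng.uniform(0.2, 50.0)),
        }
        for name in spec.names
    }


def write_cohort_fixture(
    spec: CohortSpec, seed: int, outdir: str | Path
) -> dict[str, object]:
    """Materialize a cohort on disk: FASTA files, a manifest TSV,
    conservation and compute TSVs, and a ground-truth JSON. Returns the
    ground-truth dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    assemblies, ordering = generate_cohort(spec, seed)

    manifest_lines = ["name\tlevel\tpath"]
    for asm in assemblies:
        fasta = outdir / f"{asm.name}.fasta"
        write_fasta(asm, fasta)
        manifest_lines.append(f"{asm.name}\t{asm.level.value}\t{fasta.name}")
    (outdir / "assemblies.tsv").write_text("\n".join(manifest_lines) + "\n")

    cons = conservation_for_cohort(spec, seed)
    lines = ["name\tcsg1_pct\tcsg2_pct\tcsg3_pct\tcsg4_pct"]
    for name, row in cons.items():
        lines.append(
            name
            + "\t"
            + "\t".join(f"{row[f'csg{g}_pct']:.2f}" for g in range(1, 5))
        )
    (outdir / "conservation.tsv").write_text("\n".join(lines) + "\n")

    comp = compute_for_cohort(spec, seed)
    lines = ["name\trunning_time\tpeak_memory"]
    for name, row in comp.items():
        lines.append(
            f"{name}\t{row['running_time']:.3f}\t{row['peak_memory']:.3f}"
        )
    (outdir / "compute.tsv").write_text("\n".join(lines) + "\n")

    truth = {"planted_ordering": ordering, "seed": seed}
    (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=2))
    return truth
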