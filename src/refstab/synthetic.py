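"""Synthetic Cq data, dilution series, and DE tables with known truth.

The Cq generator emulates a salt-stress style qPCR design: a panel of
genes with baselines in the 18-26 cycle range, samples laid out as
condition (control / treated) x collection time x biological replicate,
technical replicate observations per sample, i.i.d. normal replicate
noise on the cycle scale, and deterministic treatment-dependent Cq
shifts injected per (condition, time) cell.  Because shifts are
deterministic, the ground-truth stability ordering is well defined:
genes are ranked by total injected shift variation, then noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from refstab.cq_data import CqDataset

__all__ = [
    "GeneSpec",
    "CqSimSpec",
    "SyntheticTruth",
    "generate_cq_dataset",
    "generate_dilution_series",
    "generate_de_table",
    "benchmark_spec",
    "DEFAULT_TIMES",
]

DEFAULT_TIMES = ("30min", "2h", "8h", "45d")
CONDITIONS = ("control", "treated")


@dataclass
class GeneSpec:
    """One gene's generating parameters.

    ``shifts`` maps (condition, time) to a deterministic Cq offset in
    cycles; unlisted cells shift by 0.  ``treated_shift`` is a shortcut
    that applies one offset to every treated cell.
    """

    gene: str
    baseline: float  # cycles
    noise_sd: float = 0.2  # cycles, per technical replicate
    e_amp: float = 2.0
    shifts: dict[tuple[str, str], float] = field(default_factory=dict)
    treated_shift: float | None = None

    def __post_init__(self) -> None:
        if not (15.0 <= self.baseline <= 30.0):
            raise ValueError(
                f"{self.gene}: baseline {self.baseline} outside [15, 30]"
            )
        if not (0.0 <= self.noise_sd <= 2.0):
            raise ValueError(
                f"{self.gene}: noise sd {self.noise_sd} outside [0, 2]"
            )
        if not (1.0 < self.e_amp <= 2.5):
            raise ValueError(
                f"{self.gene}: amplification factor {self.e_amp} outside (1, 2.5]"
            )

    def shift_at(self, condition: str, time: str) -> float:
        if (condition, time) in self.shifts:
            return self.shifts[(condition, time)]
        if self.treated_shift is not None and condition == "treated":
            return self.treated_shift
        return 0.0


@dataclass
class CqSimSpec:
    """Layout of a simulated experiment."""

    genes: list[GeneSpec]
    times: tuple[str, ...] = DEFAULT_TIMES
    n_bio_replicates: int = 3
    n_tech_replicates: int = 3
    experiment: str = "sim"
    tissue: str = "leaf"
    #: SD (cycles) of a per-sample random intercept shared by all genes,
    #: emulating template-input variation between cDNA preparations.
    sample_effect_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.n_bio_replicates < 1 or self.n_tech_replicates < 2:
            raise ValueError(
                "need >=1 biological and >=2 technical replicates"
            )
        if not self.genes:
            raise ValueError("spec lists no genes")


@dataclass
class SyntheticTruth:
    """Injected effects and the implied ground-truth stability ordering."""

    baselines: dict[str, float]
    noise_sd: dict[str, float]
    shifts: dict[str, dict[tuple[str, str], float]]
    e_amp: dict[str, float]
    implied_ordering: list[str]  # most stable first

    def stable_genes(self) -> list[str]:
        """Genes with zero injected shift everywhere."""
        return [
            g
            for g, cell_shifts in self.shifts.items()
            if all(v == 0.0 for v in cell_shifts.values())
        ]


def _injected_variation(cell_shifts: dict[tuple[str, str], float]) -> float:
    vals = np.array(list(cell_shifts.values()), dtype=float)
    return float(np.std(vals))  # population SD across design cells


def generate_cq_dataset(
    spec: CqSimSpec, seed: int
) -> tuple[CqDataset, SyntheticTruth]:
    """Draw a replicate-level Cq dataset from ``spec``.

    Each sample is one (condition, time, biological replicate) unit with
    ``n_tech_replicates`` observations; every observation is
    baseline + shift(condition, time) + N(0, noise_sd), drawn i.i.d.
    Identical (spec, seed) pairs yield identical datasets.
    """
    rng = np.random.default_rng(seed)
    rows = []
    meta_rows = {}
    for cond in CONDITIONS:
        for time in spec.times:
            for b in range(1, spec.n_bio_replicates + 1):
                sample = f"{spec.experiment}_{time}_{cond}_b{b}"
                meta_rows[sample] = {
                    "experiment": spec.experiment,
                    "condition": cond,
                    "time": time,
                    "tissue": spec.tissue,
                }
                sample_effect = (
                    rng.normal(0.0, spec.sample_effect_sd)
                    if spec.sample_effect_sd > 0
                    else 0.0
                )
                for gs in spec.genes:
                    mu = gs.baseline + gs.shift_at(cond, time) + sample_effect
                    noise = rng.normal(0.0, gs.noise_sd, spec.n_tech_replicates)
                    for r, eps in enumerate(noise, start=1):
                        rows.append(
                            {
                                "sample": sample,
                                "gene": gs.gene,
                                "replicate": r,
                                "cq": mu + eps,
                            }
                        )
    obs = pd.DataFrame(rows)
    meta = pd.DataFrame.from_dict(meta_rows, orient="index")
    meta.index.name = "sample"
    ds = CqDataset(obs, meta, {gs.gene: gs.e_amp for gs in spec.genes})

    cells = [(c, t) for c in CONDITIONS for t in spec.times]
    shifts = {
        gs.gene: {cell: gs.shift_at(*cell) for cell in cells}
        for gs in spec.genes
    }
    order = sorted(
        spec.genes,
        key=lambda gs: (_injected_variation(shifts[gs.gene]), gs.noise_sd, gs.gene),
    )
    truth = SyntheticTruth(
        baselines={gs.gene: gs.baseline for gs in spec.genes},
        noise_sd={gs.gene: gs.noise_sd for gs in spec.genes},
        shifts=shifts,
        e_amp={gs.gene: gs.e_amp for gs in spec.genes},
        implied_ordering=[gs.gene for gs in order],
    )
    return ds, truth


def benchmark_spec(
    *,
    noise_sd: float = 0.2,
    shifts: tuple[float, ...] = (0.0, 0.0, 0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 4.0),
    times: tuple[str, ...] = DEFAULT_TIMES,
    n_bio_replicates: int = 3,
    n_tech_replicates: int = 3,
    sample_effect_sd: float = 0.5,
) -> CqSimSpec:
    """Ten-gene benchmark layout: 3 stable genes among a graded-shift ladder.

    Baselines span the 18-26 cycle range seen in real leaf/root panels.
    Shift magnitudes follow the graded ladder; their structure is chosen
    so that the injected ground truth stays identifiable by all three
    stability definitions:

    * mild shifts (< 2 cycles) are sustained condition responses whose
      signed sum over the panel is zero (+0.5, +1, -1.5 by default) —
      a panel whose unstable members all drift the same way moves the
      consensus itself, and consensus-relative metrics (NormFinder's
      inter-group term, BestKeeper's index correlation) then cannot
      distinguish "stable" from "drifting with the crowd";
    * strong shifts (>= 2 cycles) are transient responses alternating
      in sign across collection times (zero mean within the treated
      group), mimicking early/late stress kinetics.

    A per-sample random intercept (default SD 0.5 cycles) emulates
    template-input variation between cDNA preparations — the shared
    Cq covariation that raw-Cq index methods rely on; it cancels in
    log-ratio and sample-centered statistics.
    """
    baselines = (18.1, 19.2, 20.0, 20.8, 21.5, 22.3, 23.0, 23.8, 24.6, 25.8)
    # signs for sustained (mild) shifts, cycled to keep the panel balanced
    sustained_signs = (+1.0, +1.0, -1.0)
    genes = []
    n_mild = 0
    for i, s in enumerate(shifts):
        cell_shifts: dict[tuple[str, str], float] = {}
        if 0.0 < s < 2.0:
            sign = sustained_signs[n_mild % len(sustained_signs)]
            n_mild += 1
            for t in times:
                cell_shifts[("treated", t)] = sign * s
        elif s >= 2.0:
            for j, t in enumerate(times):
                cell_shifts[("treated", t)] = s * (1.0 if j % 2 == 0 else -1.0)
        genes.append(
            GeneSpec(
                gene=f"G{i + 1:02d}",
                baseline=baselines[i],
                noise_sd=noise_sd,
                shifts=cell_shifts,
            )
        )
    return CqSimSpec(
        genes=genes,
        times=times,
        n_bio_replicates=n_bio_replicates,
        n_tech_replicates=n_tech_replicates,
        sample_effect_sd=sample_effect_sd,
    )


def generate_dilution_series(
    e_amp: float,
    intercept: float,
    levels: tuple[float, ...] = (1.0, 0.1, 0.01, 0.001),
    reps: int = 3,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> list[tuple[float, float]]:
    """Simulate a serial-dilution standard curve.

    Returns (relative_input, cq) pairs with
    cq = intercept - log10(input) / log10(e_amp) + N(0, noise_sd).
    """
    if not (1.0 < e_amp <= 2.5):
        raise ValueError(f"amplification factor {e_amp} outside (1, 2.5]")
    if len(set(levels)) < 3:
        raise ValueError("need >=3 distinct dilution levels")
    rng = np.random.default_rng(seed)
    slope = -1.0 / np.log10(e_amp)
    pts = []
    for level in levels:
        mu = intercept + slope * np.log10(level)
        for _ in range(reps):
            pts.append((level, float(mu + rng.normal(0.0, noise_sd))))
    return pts


def generate_de_table(
    n_rg: int,
    n_tg: int,
    n_null: int,
    contrasts: tuple[str, ...] = ("30min", "2h", "8h", "45d"),
    seed: int | None = None,
):
    """Simulate an edgeR-style DE statistics table with known classes.

    RG-like genes are flat everywhere (|log2fc| <= 1, p > 0.05); TG-like
    genes carry one induced contrast (log2fc > 2, p < 0.05); null genes
    have a moderate induced contrast (1.2 < log2fc < 1.9 with p < 0.05)
    that violates the reference filter without meeting the target one.
    """
    from refstab.screening import DETable

    if min(n_rg, n_tg, n_null) < 0:
        raise ValueError("gene counts must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []

    def flat_row(gene, contrast):
        return {
            "gene": gene,
            "contrast": contrast,
            "log2fc": float(rng.uniform(-1.0, 1.0)),
            "pvalue": float(rng.uniform(0.2, 1.0)),
        }

    for i in range(n_rg):
        g = f"RG{i + 1:02d}"
        rows.extend(flat_row(g, c) for c in contrasts)
    for i in range(n_tg):
        g = f"TG{i + 1:02d}"
        hit = int(rng.integers(len(contrasts)))
        for j, c in enumerate(contrasts):
            if j == hit:
                rows.append(
                    {
                        "gene": g,
                        "contrast": c,
                        "log2fc": float(rng.uniform(2.5, 4.0)),
                        "pvalue": float(rng.uniform(0.001, 0.04)),
                    }
                )
            else:
                rows.append(flat_row(g, c))
    for i in range(n_null):
        g = f"NULL{i + 1:02d}"
        hit = int(rng.integers(len(contrasts)))
        for j, c in enumerate(contrasts):
            if j == hit:
                rows.append(
                    {
                        "gene": g,
                        "contrast": c,
                        "log2fc": float(rng.uniform(1.2, 1.9)),
                        "pvalue": float(rng.uniform(0.001, 0.04)),
                    }
                )
            else:
                rows.append(flat_row(g, c))
    return DETable(pd.DataFrame(rows))
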