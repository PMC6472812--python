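"""Cq data model, I/O, and the relative-quantity transform.

A qPCR run yields one quantification cycle (Cq) per well; biological and
technical replicates of the same sample x gene combination are collapsed
to a per-sample mean before any stability statistic is computed.  All
downstream algorithms that work on a linear abundance scale consume the
relative quantity

    Q[g, s] = E_g ** (minCq_g - meanCq[g, s])

where ``E_g`` is the gene's amplification factor (2.0 = perfect doubling)
and the calibrator is the per-gene minimum mean Cq, so that each gene's
maximum Q is exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CqDataset",
    "QuantityMatrix",
    "read_cq_table",
    "write_cq_table",
    "read_efficiencies",
    "relative_quantities",
]

#: Columns every long-format Cq table must provide.
REQUIRED_COLUMNS = ("sample", "gene", "replicate", "cq")

#: Optional per-sample metadata columns recognised in long format.
META_COLUMNS = ("experiment", "condition", "time", "tissue")


class CqValidationError(ValueError):
    """Raised when a Cq table violates the data-model invariants."""


@dataclass
class CqDataset:
    """Replicate-level quantification cycles plus sample metadata.

    Parameters
    ----------
    observations:
        Long DataFrame with columns ``sample, gene, replicate, cq``.
    sample_meta:
        One row per sample (index = sample id) with columns
        ``experiment, condition, time, tissue`` (missing ones filled
        with empty strings).  ``condition`` is conventionally
        ``control`` or ``treated``.
    efficiencies:
        Per-gene amplification factor E_amp, dimensionless, in (1, 2.5].
    """

    observations: pd.DataFrame
    sample_meta: pd.DataFrame
    efficiencies: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        obs = self.observations
        missing = [c for c in REQUIRED_COLUMNS if c not in obs.columns]
        if missing:
            raise CqValidationError(f"observations missing columns: {missing}")
        cq = pd.to_numeric(obs["cq"], errors="coerce")
        bad = ~np.isfinite(cq) | (cq <= 0)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise CqValidationError(
                f"non-numeric or non-positive cq at row {row} "
                f"(sample={obs.iloc[row]['sample']}, gene={obs.iloc[row]['gene']})"
            )
        self.observations = obs.assign(cq=cq.astype(float))
        meta = self.sample_meta.copy()
        for col in META_COLUMNS:
            if col not in meta.columns:
                meta[col] = ""
        self.sample_meta = meta
        orphans = set(obs["sample"]) - set(meta.index)
        if orphans:
            raise CqValidationError(
                f"samples without metadata: {sorted(map(str, orphans))}"
            )
        for gene, e in self.efficiencies.items():
            if not (1.0 < e <= 2.5):
                raise CqValidationError(
                    f"efficiency for {gene} must be in (1, 2.5], got {e}"
                )

    @property
    def genes(self) -> list[str]:
        return sorted(self.observations["gene"].unique())

    @property
    def samples(self) -> list[str]:
        return sorted(self.observations["sample"].unique())

    def mean_cq(self, min_replicates: int = 1) -> pd.DataFrame:
        """Per-sample replicate-mean Cq as a gene x sample grid.

        Cells backed by fewer than ``min_replicates`` surviving
        replicates become NaN (missing) and are propagated as such.
        """
        grp = self.observations.groupby(["gene", "sample"])["cq"]
        means = grp.mean().unstack("sample")
        if min_replicates > 1:
            counts = grp.count().unstack("sample")
            means = means.where(counts >= min_replicates)
        return means.reindex(index=self.genes, columns=self.samples)

    def subset_samples(self, sample_ids) -> "CqDataset":
        """Restrict to the given samples, keeping metadata and efficiencies."""
        keep = set(sample_ids)
        obs = self.observations[self.observations["sample"].isin(keep)]
        meta = self.sample_meta.loc[self.sample_meta.index.isin(keep)]
        return CqDataset(obs.reset_index(drop=True), meta, dict(self.efficiencies))

    def condition_of(self, sample: str) -> str:
        return str(self.sample_meta.loc[sample, "condition"])

    def time_of(self, sample: str) -> str:
        return str(self.sample_meta.loc[sample, "time"])


@dataclass
class QuantityMatrix:
    """Gene x sample grid of relative quantities Q, per-gene max exactly 1."""

    values: pd.DataFrame  # index = gene ids, columns = sample ids

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.any(v[np.isfinite(v)] <= 0):
                raise CqValidationError("relative quantities must be positive")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_genes(self, genes) -> "QuantityMatrix":
        return QuantityMatrix(self.values.loc[list(genes)])

    def subset_samples(self, samples) -> "QuantityMatrix":
        return QuantityMatrix(self.values[list(samples)])


def _meta_from_long(df: pd.DataFrame) -> pd.DataFrame:
    """Extract one metadata row per sample from a long table."""
    cols = [c for c in META_COLUMNS if c in df.columns]
    meta = (
        df[["sample", *cols]]
        .drop_duplicates(subset="sample")
        .set_index("sample")
    )
    dup = df[["sample", *cols]].drop_duplicates()
    if dup["sample"].duplicated().any():
        bad = dup.loc[dup["sample"].duplicated(), "sample"].iloc[0]
        raise CqValidationError(f"inconsistent metadata for sample {bad!r}")
    return meta


def read_cq_table(
    path,
    *,
    metadata_path=None,
    efficiencies: dict[str, float] | None = None,
    sep: str | None = None,
) -> CqDataset:
    """Read a Cq table from disk.

    Two encodings are accepted:

    * long format — columns ``sample, gene, replicate, cq`` plus optional
      metadata columns (``experiment, condition, time, tissue``);
    * wide format — a gene x sample matrix (first column = gene id,
      remaining columns = sample ids) together with a required sidecar
      ``metadata_path`` table holding one row per sample.

    Replicate Cq values are never collapsed here; averaging happens only
    where an algorithm asks for :meth:`CqDataset.mean_cq`.
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    long_format = all(c in df.columns for c in REQUIRED_COLUMNS)
    if long_format:
        if metadata_path is not None:
            meta = pd.read_csv(metadata_path, sep=sep).set_index("sample")
        else:
            meta = _meta_from_long(df)
        obs = df[list(REQUIRED_COLUMNS)].copy()
    else:
        if metadata_path is None:
            raise CqValidationError(
                "wide-format Cq matrix requires a sample metadata sidecar"
            )
        meta = pd.read_csv(metadata_path, sep=sep).set_index("sample")
        gene_col = df.columns[0]
        long = df.melt(id_vars=gene_col, var_name="sample", value_name="cq")
        long = long.rename(columns={gene_col: "gene"})
        long["replicate"] = 1
        obs = long[["sample", "gene", "replicate", "cq"]]
    return CqDataset(obs.reset_index(drop=True), meta, efficiencies or {})


def write_cq_table(ds: CqDataset, path, sep: str = ",") -> None:
    """Write a dataset back to long format, metadata columns inlined.

    Floats are rendered with :func:`repr`-fidelity so that a
    read -> write -> read round trip reproduces every Cq exactly.
    """
    obs = ds.observations.copy()
    meta = ds.sample_meta.reindex(obs["sample"]).reset_index(drop=True)
    for col in META_COLUMNS:
        obs[col] = meta[col].to_numpy()
    obs.to_csv(path, sep=sep, index=False, float_format=None)


def read_efficiencies(path, *, percent: bool | None = None) -> dict[str, float]:
    """Read per-gene efficiencies from a two-column CSV.

    Accepts either the amplification factor (column ``e_amp``, values
    near 2) or percent efficiency (column ``e_percent``, values near
    100).  With generic headers the scale is auto-detected by magnitude
    (values > 5 are treated as percent); pass ``percent=`` to override.
    """
    df = pd.read_csv(path)
    gene_col = df.columns[0]
    val_col = df.columns[1]
    vals = df[val_col].astype(float)
    if percent is None:
        if val_col.lower() in {"e_amp", "eamp", "efficiency_factor"}:
            percent = False
        elif val_col.lower() in {"e_percent", "epercent", "percent"}:
            percent = True
        else:
            percent = bool((vals > 5).all())
    if percent:
        vals = 1.0 + vals / 100.0
    return dict(zip(df[gene_col].astype(str), vals))


def relative_quantities(
    ds: CqDataset,
    *,
    default_efficiency: float | None = None,
    calibrator_sample: str | None = None,
    min_replicates: int = 1,
) -> QuantityMatrix:
    """Transform mean Cq values into relative quantities Q = E**dCq.

    dCq is measured against the per-gene minimum mean Cq (the most
    abundant sample), so Q is in (0, 1] with per-gene maximum exactly 1.
    Passing ``calibrator_sample`` pins the calibrator to an explicit
    sample instead (Q may then exceed 1).  Missing gene x sample cells
    stay missing.
    """
    means = ds.mean_cq(min_replicates=min_replicates)
    q = pd.DataFrame(
        np.nan, index=means.index, columns=means.columns, dtype=float
    )
    for gene in means.index:
        e = ds.efficiencies.get(gene, default_efficiency)
        if e is None:
            raise CqValidationError(
                f"no amplification efficiency for gene {gene!r} "
                "and no default provided"
            )
        row = means.loc[gene]
        if calibrator_sample is not None:
            cal = row[calibrator_sample]
        else:
            cal = row.min()
        q.loc[gene] = np.power(e, cal - row)
        if calibrator_sample is None and row.notna().any():
            # guard against float round-off at the calibrator cell
            q.loc[gene, row.idxmin()] = 1.0
    return QuantityMatrix(q)
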