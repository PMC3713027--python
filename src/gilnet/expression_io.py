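"""Expression-matrix I/O, probe filtering, normalization and sample QC.

The compendium is a samples x probesets matrix of log2-scale intensities.
Before any network is built, control probesets and ambiguous probesets
(those mapping to more than one gene locus) are removed, samples are
quantile-normalized, and outlier arrays failing at least two of three
quality statistics are dropped.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionMatrix",
    "ProbeGeneMap",
    "QCReport",
    "load_expression_matrix",
    "save_expression_matrix",
    "load_probe_gene_map",
    "filter_probesets",
    "quantile_normalize",
    "detect_outlier_samples",
    "remove_samples",
]


@dataclass
class ExpressionMatrix:
    """A samples x probesets intensity matrix (log2 scale).

    Attributes
    ----------
    sample_ids : list of str
        Row identifiers (microarray/sample names), unique.
    probe_ids : list of str
        Column identifiers (probeset names), unique.
    values : ndarray of shape (n_samples, n_probes)
        Finite intensities; missing values are rejected at load time.
    metadata : dict
        Free-form per-sample annotations.
    """

    sample_ids: list[str]
    probe_ids: list[str]
    values: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.probe_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.probe_ids)} probes"
            )
        for name, ids in (("sample", self.sample_ids), ("probe", self.probe_ids)):
            dup = _duplicates(ids)
            if dup:
                raise ValueError(f"duplicate {name} identifiers: {sorted(dup)}")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                "non-finite value at sample "
                f"{self.sample_ids[bad[0]]!r}, probe {self.probe_ids[bad[1]]!r}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.probe_ids)

    def subset_samples(self, keep: list[str]) -> "ExpressionMatrix":
        idx = [self.sample_ids.index(s) for s in keep]
        return ExpressionMatrix(
            [self.sample_ids[i] for i in idx],
            list(self.probe_ids),
            self.values[idx],
            dict(self.metadata),
        )

    def subset_probes(self, keep: list[str]) -> "ExpressionMatrix":
        idx = [self.probe_ids.index(p) for p in keep]
        return ExpressionMatrix(
            list(self.sample_ids),
            [self.probe_ids[i] for i in idx],
            self.values[:, idx],
            dict(self.metadata),
        )


@dataclass
class ProbeGeneMap:
    """Mapping from probeset id to the gene loci it hybridizes to."""

    gene_ids: dict[str, list[str]]  # probe -> loci
    control: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for probe, genes in self.gene_ids.items():
            if any(not isinstance(g, str) or not g for g in genes):
                raise ValueError(f"empty gene identifier for probe {probe!r}")

    def loci(self, probe: str) -> list[str]:
        return self.gene_ids.get(probe, [])

    def is_ambiguous(self, probe: str) -> bool:
        return len(self.gene_ids.get(probe, [])) > 1

    def gene_of(self, probe: str) -> str | None:
        loci = self.gene_ids.get(probe, [])
        return loci[0] if len(loci) == 1 else None


@dataclass
class QCReport:
    """Record of probes and samples removed during quality control."""

    removed_control_probes: list[str] = field(default_factory=list)
    removed_ambiguous_probes: list[str] = field(default_factory=list)
    outlier_samples: list[str] = field(default_factory=list)
    outlier_flags: dict[str, tuple[bool, bool, bool]] = field(default_factory=dict)

    @property
    def removed_controls(self) -> int:
        return len(self.removed_control_probes)

    @property
    def removed_ambiguous(self) -> int:
        return len(self.removed_ambiguous_probes)

    def to_json(self) -> str:
        return json.dumps(
            {
                "removed_controls": self.removed_controls,
                "removed_ambiguous": self.removed_ambiguous,
                "control_probes": self.removed_control_probes,
                "ambiguous_probes": self.removed_ambiguous_probes,
                "outlier_samples": self.outlier_samples,
                "outlier_flags": {s: list(map(bool, f)) for s, f in self.outlier_flags.items()},
            },
            indent=2,
        )


def _duplicates(ids) -> set:
    seen, dup = set(), set()
    for x in ids:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


def load_expression_matrix(
    path, *, samples_as_rows: bool = True, log2: bool = False
) -> ExpressionMatrix:
    """Read a TSV expression matrix.

    The first row holds probe ids and the first column sample ids (set
    ``samples_as_rows=False`` for the transposed layout). With ``log2``
    the transform log2(x + 1) is applied after reading.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    dup = _duplicates(header)  # pandas mangles duplicate columns, so check raw
    if dup:
        name = "probe" if samples_as_rows else "sample"
        raise ValueError(f"duplicate {name} identifiers in {path}: {sorted(dup)}")
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if not samples_as_rows:
        df = df.T
    for axis, name in ((df.index, "sample"), (df.columns, "probe")):
        dup = _duplicates(axis)
        if dup:
            raise ValueError(f"duplicate {name} identifiers in {path}: {sorted(dup)}")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        for j, col in enumerate(df.columns):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                i = int(np.argmax(bad.to_numpy()))
                raise ValueError(
                    f"non-numeric cell at sample {df.index[i]!r}, probe {col!r}: "
                    f"{df[col].iloc[i]!r}"
                )
        values = df.apply(pd.to_numeric).to_numpy()
    if pd.isna(values).any():
        i, j = np.argwhere(pd.isna(values))[0]
        raise ValueError(
            f"missing value at sample {df.index[i]!r}, probe {df.columns[j]!r}"
        )
    values = values.astype(float)
    if log2:
        values = np.log2(values + 1.0)
    return ExpressionMatrix(list(df.index.astype(str)), list(df.columns.astype(str)), values)


def save_expression_matrix(m: ExpressionMatrix, path) -> None:
    """Write a TSV matrix (probes as columns) round-trippable by the loader."""
    m.to_frame().to_csv(path, sep="\t", index_label="sample_id")


def load_probe_gene_map(path) -> ProbeGeneMap:
    """Read a probe map TSV with columns probe_id, gene_id (one row per mapping)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"probe_id", "gene_id"} <= set(df.columns):
        raise ValueError("probe map must have columns probe_id and gene_id")
    mapping: dict[str, list[str]] = {}
    for probe, gene in zip(df["probe_id"], df["gene_id"]):
        mapping.setdefault(probe, [])
        if gene not in mapping[probe]:
            mapping[probe].append(gene)
    return ProbeGeneMap(mapping)


def filter_probesets(
    m: ExpressionMatrix,
    probe_map: ProbeGeneMap,
    control_patterns: list[str] = ("AFFX",),
) -> tuple[ExpressionMatrix, QCReport]:
    """Drop control and ambiguous probesets.

    A probe is a control if its id starts with any of ``control_patterns``
    or is flagged in the map; ambiguous if it maps to more than one gene
    locus. Probes absent from the map are treated as ambiguous (removed
    with a warning): they cannot be placed on the genome.
    """
    report = QCReport()
    keep = []
    unmapped = []
    for probe in m.probe_ids:
        if any(probe.startswith(pat) for pat in control_patterns) or probe in probe_map.control:
            report.removed_control_probes.append(probe)
        elif probe not in probe_map.gene_ids:
            unmapped.append(probe)
            report.removed_ambiguous_probes.append(probe)
        elif probe_map.is_ambiguous(probe):
            report.removed_ambiguous_probes.append(probe)
        else:
            keep.append(probe)
    if unmapped:
        warnings.warn(
            f"{len(unmapped)} probes absent from the probe map were removed "
            "(treated as ambiguous)",
            stacklevel=2,
        )
    if not keep:
        raise ValueError("no informative probes remain after filtering")
    return m.subset_probes(keep), report


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the common (cross-sample mean) quantile profile.

    After normalization every sample's sorted intensity vector is identical
    and the value at rank r is the mean over samples of their rank-r values.
    """
    if m.n_samples < 2:
        warnings.warn("quantile normalization skipped: fewer than 2 samples", stacklevel=2)
        return m
    order = np.argsort(m.values, axis=1, kind="stable")
    ranks = np.empty_like(order)
    rows = np.arange(m.n_samples)[:, None]
    ranks[rows, order] = np.arange(m.n_probes)[None, :]
    mean_profile = np.sort(m.values, axis=1).mean(axis=0)
    normalized = mean_profile[ranks]
    return ExpressionMatrix(list(m.sample_ids), list(m.probe_ids), normalized, dict(m.metadata))


def _fence_flags(statistic: np.ndarray) -> np.ndarray:
    """Flag values above Tukey's upper fence Q3 + 1.5*IQR."""
    q1, q3 = np.percentile(statistic, [25, 75])
    return statistic > q3 + 1.5 * (q3 - q1)


def detect_outlier_samples(m: ExpressionMatrix) -> QCReport:
    """Flag outlier arrays failing at least two of three tests.

    The three statistics, each turned into a flag by the Tukey upper fence
    (Q3 + 1.5*IQR) over samples:

    T1. mean Euclidean distance to all other samples;
    T2. Kolmogorov-Smirnov statistic between the sample's intensity ECDF
        and the pooled ECDF of all samples;
    T3. 1 - median Pearson correlation with all other samples.

    A sample is an outlier iff flagged by >= 2 tests.
    """
    n = m.n_samples
    if n < 4:
        raise ValueError("outlier detection needs at least 4 samples (IQR fences undefined)")
    X = m.values

    sq = (X * X).sum(axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2 * X @ X.T, 0.0)
    dist = np.sqrt(d2)
    t1 = dist.sum(axis=1) / (n - 1)

    pooled = np.sort(X.ravel())
    t2 = np.empty(n)
    for i in range(n):
        t2[i] = stats.ks_2samp(X[i], pooled, method="asymp").statistic

    corr = np.corrcoef(X)
    np.fill_diagonal(corr, np.nan)
    t3 = 1.0 - np.nanmedian(corr, axis=1)

    flags = np.column_stack([_fence_flags(t1), _fence_flags(t2), _fence_flags(t3)])
    report = QCReport()
    for i, sample in enumerate(m.sample_ids):
        f = tuple(bool(x) for x in flags[i])
        report.outlier_flags[sample] = f
        if sum(f) >= 2:
            report.outlier_samples.append(sample)
    return report


def remove_samples(m: ExpressionMatrix, drop: list[str]) -> ExpressionMatrix:
    keep = [s for s in m.sample_ids if s not in set(drop)]
    return m.subset_samples(keep)
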