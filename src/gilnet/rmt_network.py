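"""Per-group co-expression network construction with RMT thresholding.

For one pre-clustered sample group the all-pairs Pearson correlation
matrix is computed, then a hard threshold is discovered with the random
matrix theory (RMT) criterion: as the threshold rises, the eigenvalue
nearest-neighbour spacing distribution (NNSD) of the thresholded matrix
transitions from Wigner/GOE-like (random) to Poisson (modular).  The
chosen threshold is the smallest one at which a chi-square test accepts
the Poisson form at p = 0.001.  Edges at or above the threshold form one
Gene Interaction Layer (GIL).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.stats import chi2 as chi2_dist

from gilnet.expression_io import ExpressionMatrix, ProbeGeneMap

__all__ = [
    "SimilarityMatrix",
    "RMTScanResult",
    "GILNetwork",
    "correlation_matrix",
    "unfold_eigenvalues",
    "nnsd_chi_square",
    "find_rmt_threshold",
    "build_network",
    "network_summary",
    "collection_summary",
]

#: minimum distinct eigenvalues for a testable NNSD
MIN_EIGENVALUES = 100
#: tolerance below which consecutive eigenvalues are considered degenerate
DEDUP_TOL = 1e-6


@dataclass
class SimilarityMatrix:
    """Symmetric Pearson correlation matrix over probes (or genes)."""

    ids: list[str]
    r: np.ndarray  # (n, n), unit diagonal, |r| <= 1
    n_samples: int
    mean_intensity: np.ndarray | None = None  # used to collapse probes to genes

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        n = len(self.ids)
        if self.r.shape != (n, n):
            raise ValueError("similarity matrix shape does not match ids")


@dataclass
class RMTScanResult:
    """Diagnostics of the threshold scan.

    ``scan`` rows record, per candidate threshold: surviving matrix size,
    distinct-eigenvalue count, the NNSD chi-square statistic against the
    Poisson expectation, and the accept/reject decision.
    """

    scan: list[dict] = field(default_factory=list)
    threshold: float | None = None
    failure: str | None = None  # no_threshold_found | too_few_genes

    @property
    def success(self) -> bool:
        return self.threshold is not None


@dataclass
class GILNetwork:
    """One thresholded co-expression network (a Gene Interaction Layer)."""

    gil_id: str
    edges: list[tuple[str, str, float]]  # (gene_a, gene_b, signed r), a < b
    threshold: float
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for a, b, r in self.edges:
            if a == b:
                raise ValueError(f"self-loop on {a}")
            if (a, b) in seen:
                raise ValueError(f"duplicate edge {a}-{b}")
            seen.add((a, b))
            if abs(r) < self.threshold - 1e-12:
                raise ValueError(f"edge {a}-{b} has |r|={abs(r):.4f} below threshold")

    @property
    def nodes(self) -> set[str]:
        return {g for a, b, _ in self.edges for g in (a, b)}

    @property
    def edge_set(self) -> set[tuple[str, str]]:
        return {(a, b) for a, b, _ in self.edges}

    def neighbors(self) -> dict[str, set[str]]:
        adj: dict[str, set[str]] = {}
        for a, b, _ in self.edges:
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)
        return adj

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph(gil_id=self.gil_id, threshold=self.threshold)
        for a, b, r in self.edges:
            g.add_edge(a, b, r=r, abs_r=abs(r))
        return g

    def write_edge_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_a\tgene_b\tr\tabs_r\n")
            for a, b, r in sorted(self.edges):
                fh.write(f"{a}\t{b}\t{r:.6f}\t{abs(r):.6f}\n")


def correlation_matrix(m: ExpressionMatrix) -> SimilarityMatrix:
    """All-pairs Pearson correlation of probes across the group's samples.

    Zero-variance probes cannot be correlated and are dropped with a
    warning.  Requires at least 3 samples.
    """
    if m.n_samples < 3:
        raise ValueError("correlation needs at least 3 samples")
    var = m.values.var(axis=0)
    keep = var > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance probes", stacklevel=2)
    ids = [p for p, k in zip(m.probe_ids, keep) if k]
    X = m.values[:, keep]
    r = np.corrcoef(X, rowvar=False)
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)
    return SimilarityMatrix(ids, r, m.n_samples, mean_intensity=X.mean(axis=0))


def _dedup(eigenvalues: np.ndarray, tol: float = DEDUP_TOL) -> np.ndarray:
    """Collapse near-degenerate eigenvalues (within ``tol``) to one value."""
    ev = np.sort(np.asarray(eigenvalues, dtype=float))
    keep = [ev[0]]
    for x in ev[1:]:
        if x - keep[-1] > tol:
            keep.append(x)
    return np.asarray(keep)


def unfold_eigenvalues(eigenvalues: np.ndarray, knot_every: int = 10, min_knots: int = 5) -> np.ndarray:
    """Map eigenvalues onto a uniform density scale (mean spacing 1).

    A monotone cubic (PCHIP) spline is fitted to the empirical cumulative
    spectral function at every ``knot_every``-th distinct eigenvalue and
    evaluated at every eigenvalue; spacings of the result are then
    normalized to mean exactly 1.
    """
    ev = _dedup(eigenvalues)
    n = len(ev)
    if n < 3:
        raise ValueError("too few distinct eigenvalues to unfold")
    cum = np.arange(1, n + 1, dtype=float)
    idx = list(range(0, n, knot_every))
    if idx[-1] != n - 1:
        idx.append(n - 1)
    if len(idx) < min_knots:
        idx = list(range(n))
    spline = PchipInterpolator(ev[idx], cum[idx])
    unfolded = np.asarray(spline(ev), dtype=float)
    spacings = np.diff(unfolded)
    mean = spacings.mean()
    if mean <= 0:
        raise ValueError("degenerate spectrum: unfolding produced non-positive mean spacing")
    return unfolded / mean


def nnsd_chi_square(
    eigenvalues: np.ndarray,
    n_bins: int = 60,
    *,
    min_eigenvalues: int = MIN_EIGENVALUES,
    s_max: float = 3.0,
) -> float:
    """Chi-square statistic of the NNSD against the Poisson form e^(-s).

    Eigenvalues are deduplicated and unfolded; the spacings (mean 1) are
    binned into ``n_bins`` bins spanning [0, ``s_max``] with larger
    spacings pooled into the last bin, and compared with the expected
    Poisson bin masses.  Small statistic = Poisson-like (modular matrix);
    large = level repulsion (random, GOE-like).
    """
    ev = _dedup(eigenvalues)
    if len(ev) < min_eigenvalues:
        raise ValueError(
            f"too_few_genes: {len(ev)} distinct eigenvalues < required {min_eigenvalues}"
        )
    spacings = np.diff(unfold_eigenvalues(ev))
    return _poisson_chi_square(spacings, n_bins=n_bins, s_max=s_max)


def _poisson_chi_square(spacings: np.ndarray, n_bins: int = 60, s_max: float = 3.0) -> float:
    edges = np.linspace(0.0, s_max, n_bins + 1)
    observed, _ = np.histogram(np.minimum(spacings, s_max - 1e-12), bins=edges)
    p = np.exp(-edges[:-1]) - np.exp(-edges[1:])
    p[-1] += np.exp(-s_max)  # pooled tail
    expected = len(spacings) * p
    return float(((observed - expected) ** 2 / expected).sum())


def nnsd_critical_value(p: float = 0.001, n_bins: int = 60) -> float:
    """Chi-square critical value at significance ``p`` with df = n_bins - 1."""
    return float(chi2_dist.ppf(1.0 - p, df=n_bins - 1))


def _threshold_state(r: np.ndarray, t: float) -> tuple[np.ndarray, int]:
    """Zero sub-threshold entries; keep genes with >= 1 surviving partner."""
    mask = np.abs(r) >= t
    np.fill_diagonal(mask, False)
    alive = mask.any(axis=0)
    n_alive = int(alive.sum())
    if n_alive == 0:
        return np.empty((0, 0)), 0
    sub = np.where(mask[np.ix_(alive, alive)], r[np.ix_(alive, alive)], 0.0)
    np.fill_diagonal(sub, 1.0)
    return sub, n_alive


def _evaluate_threshold(
    r: np.ndarray, t: float, p: float, n_bins: int, min_eigenvalues: int
) -> dict:
    sub, n_alive = _threshold_state(r, t)
    row = {"t": round(t, 6), "n_genes": n_alive, "n_eigenvalues": 0, "chi2": None}
    if n_alive < min_eigenvalues:
        row["decision"] = "too_few_genes"
        return row
    ev = _dedup(np.linalg.eigvalsh(sub))
    row["n_eigenvalues"] = len(ev)
    if len(ev) < min_eigenvalues:
        row["decision"] = "too_few_genes"
        return row
    chi2 = nnsd_chi_square(ev, n_bins=n_bins, min_eigenvalues=min_eigenvalues)
    row["chi2"] = chi2
    row["decision"] = "accept" if chi2 <= nnsd_critical_value(p, n_bins) else "reject"
    return row


def find_rmt_threshold(
    s: SimilarityMatrix,
    t_start: float = 0.50,
    t_step: float = 0.01,
    refine_step: float = 0.001,
    p: float = 0.001,
    *,
    n_bins: int = 60,
    min_eigenvalues: int = MIN_EIGENVALUES,
) -> RMTScanResult:
    """Scan thresholds upward until the NNSD first accepts the Poisson form.

    At each candidate t the genes with at least one off-diagonal |r| >= t
    are kept, sub-threshold entries zeroed (unit diagonal), and the NNSD
    chi-square computed.  The chosen threshold is the smallest accepting t,
    refined to ``refine_step`` between the last rejecting and the first
    accepting coarse candidate.

    The scan looks for the random-to-modular *transition*: an acceptance
    must be preceded by a rejection at a lower candidate.  If the very
    first candidate already accepts there is no transition inside the
    grid to locate (an already-fragmented matrix — e.g. sparse noise —
    has a Poisson NNSD everywhere), and the scan reports failure.
    Failure is a data outcome, not an error: ``no_threshold_found`` if no
    transition exists in (t_start, 1), ``too_few_genes`` if the surviving
    matrix shrinks below ``min_eigenvalues`` before acceptance.
    """
    result = RMTScanResult()
    last_reject_t = None
    coarse_accept_t = None
    t = t_start
    while t < 1.0 - 1e-9:
        row = _evaluate_threshold(s.r, t, p, n_bins, min_eigenvalues)
        result.scan.append(row)
        if row["decision"] == "too_few_genes":
            # nothing was ever testable -> there was no threshold to find;
            # shrinking below the minimum mid-scan is the too_few_genes outcome
            tested = any(r["decision"] in ("accept", "reject") for r in result.scan)
            result.failure = "too_few_genes" if tested else "no_threshold_found"
            return result
        if row["decision"] == "accept":
            if last_reject_t is None:
                # accepted at the scan start: no transition observed
                result.failure = "no_threshold_found"
                return result
            coarse_accept_t = t
            break
        last_reject_t = t
        t = round(t + t_step, 10)
    if coarse_accept_t is None:
        result.failure = "no_threshold_found"
        return result

    chosen = coarse_accept_t
    if last_reject_t is not None and refine_step < t_step:
        t = round(last_reject_t + refine_step, 10)
        while t < coarse_accept_t - 1e-9:
            row = _evaluate_threshold(s.r, t, p, n_bins, min_eigenvalues)
            result.scan.append(row)
            if row["decision"] == "accept":
                chosen = t
                break
            t = round(t + refine_step, 10)
    result.scan.sort(key=lambda r: r["t"])
    result.threshold = round(chosen, 6)
    return result


def _collapse_probes(s: SimilarityMatrix, probe_map: ProbeGeneMap) -> tuple[list[str], np.ndarray]:
    """Map probes to genes, keeping the highest-mean-intensity probe per gene."""
    best: dict[str, int] = {}
    intensity = (
        s.mean_intensity if s.mean_intensity is not None else np.zeros(len(s.ids))
    )
    for i, probe in enumerate(s.ids):
        gene = probe_map.gene_of(probe)
        if gene is None:
            continue  # ambiguous/control/unmapped probes never reach a network
        if gene not in best or intensity[i] > intensity[best[gene]]:
            best[gene] = i
    genes = sorted(best)
    idx = [best[g] for g in genes]
    return genes, s.r[np.ix_(idx, idx)]


def build_network(
    s: SimilarityMatrix,
    t: float,
    probe_map: ProbeGeneMap | None = None,
    gil_id: str = "G0001",
) -> GILNetwork:
    """Extract the thresholded graph: one edge per pair with |r| >= t.

    With a probe map, probes are first collapsed to genes (one probe per
    gene: the one with highest mean intensity).  Isolated genes are not
    part of the node set.  Signed r is stored on every edge.
    """
    if not (0.0 < t < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    if probe_map is not None:
        ids, r = _collapse_probes(s, probe_map)
    else:
        ids, r = list(s.ids), s.r
    iu, ju = np.triu_indices(len(ids), k=1)
    hit = np.abs(r[iu, ju]) >= t
    edges = []
    for i, j in zip(iu[hit], ju[hit]):
        a, b = ids[i], ids[j]
        if a > b:
            a, b = b, a
        edges.append((a, b, float(r[i, j])))
    if not edges:
        warnings.warn(f"{gil_id}: no edge survives threshold {t}", stacklevel=2)
    return GILNetwork(gil_id, sorted(edges), t)


def average_degree(n_edges: int, n_nodes: int) -> float:
    """Average degree <k> = 2E/N, reported to 2 decimals (0 for empty graphs)."""
    return round(2 * n_edges / n_nodes, 2) if n_nodes else 0.0


def network_summary(net: GILNetwork) -> dict:
    """Node/edge counts, average degree 2E/N (2 decimals) and degree distribution."""
    n_nodes = len(net.nodes)
    n_edges = len(net.edges)
    degrees = Counter()
    for a, b, _ in net.edges:
        degrees[a] += 1
        degrees[b] += 1
    avg_degree = average_degree(n_edges, n_nodes)
    return {
        "gil_id": net.gil_id,
        "nodes": n_nodes,
        "edges": n_edges,
        "threshold": net.threshold,
        "avg_degree": avg_degree,
        "degree_distribution": dict(Counter(degrees.values())),
    }


def collection_summary(nets: list[GILNetwork]) -> dict:
    """Node/edge redundancy across a GIL collection.

    Counts how many nodes (edges) appear in exactly m of the networks;
    totals are distinct nodes and summed edges; fractions are rounded to
    whole percent.
    """
    if not nets:
        raise ValueError("need at least one network")
    node_mult = Counter()
    edge_mult = Counter()
    for net in nets:
        for g in net.nodes:
            node_mult[g] += 1
        for e in net.edge_set:
            edge_mult[e] += 1
    nodes_per_m = Counter(node_mult.values())
    edges_per_m = Counter(edge_mult.values())
    n_distinct_nodes = len(node_mult)
    total_edges = sum(len(net.edges) for net in nets)
    n_distinct_edges = len(edge_mult)
    return {
        "nodes_by_multiplicity": dict(sorted(nodes_per_m.items())),
        "edges_by_multiplicity": dict(sorted(edges_per_m.items())),
        "distinct_nodes": n_distinct_nodes,
        "distinct_edges": n_distinct_edges,
        "total_edges": total_edges,
        "node_fraction_by_multiplicity": {
            m: round(100 * c / n_distinct_nodes) for m, c in sorted(nodes_per_m.items())
        },
        "edge_fraction_by_multiplicity": {
            m: round(100 * c / n_distinct_edges) for m, c in sorted(edges_per_m.items())
        },
    }
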