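"""Transcriptional response-type taxonomy and its permutation test.

Each gene's time course is discretized into a qualitative state at the
three phase transitions — ND (t2 vs t1), CD (t3 vs t2) and pCD (t4 vs
t3): U (significantly up at least ``fold_threshold``-fold), D
(significantly down), or S (sustained). The resulting triple over
{U, D, S} maps to one of 27 canonical response types, enumerated by the
earliest transition of change with upregulation prioritized over
downregulation, complementary (U <-> D mirrored) patterns adjacent, and
the all-sustained triple last (it is never counted among the "changing"
types).

Co-expression clustering is guided by an annotation hierarchy: genes
are grouped within their most specific annotation node by
single-linkage on the Pearson correlation of their per-time-point mean
profiles, so co-expression is only asserted among functionally related
genes. Cluster ids are carried as metadata; the classification itself
is per gene and independent of clustering granularity.

Significance of a response type is assessed by a permutation test of
time points: sample time labels are shuffled (group sizes preserved),
the pairwise-DE -> classify -> count chain is re-run, and the observed
count of SOM-interaction genes in the type is compared with its null
distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import hypergeom

from .errors import AnnotationError
from .expression import (
    DEFAULT_ALPHA,
    DEFAULT_MIN_DISPERSION,
    DEFAULT_PSEUDOCOUNT,
    size_factors,
    test_pairwise,
)

__all__ = [
    "AnnotationHierarchy", "build_hierarchy", "cluster_genes",
    "classify_response", "classify_profiles", "count_types",
    "permutation_test", "PermutationResult", "RESPONSE_TYPE_ORDER",
    "response_type_id", "SUSTAINED_TYPE_ID", "TRANSITIONS",
]

#: Transition labels in temporal order.
TRANSITIONS = ("ND", "CD", "pCD")

DEFAULT_FOLD_THRESHOLD = 2.0
DEFAULT_CORR_THRESHOLD = 0.8

_FLIP = {"U": "D", "D": "U", "S": "S"}
_RANK = {"U": 0, "S": 1, "D": 2}


def _canonical_order() -> tuple[tuple[str, str, str], ...]:
    changing = [t for t in product("UDS", repeat=3) if t != ("S", "S", "S")]

    def first_change(t):
        return next(i for i, s in enumerate(t) if s != "S")

    ordered: list[tuple[str, str, str]] = []
    seen: set[tuple[str, str, str]] = set()
    for t in sorted(changing, key=lambda t: (first_change(t),
                                             tuple(_RANK[s] for s in t))):
        if t in seen:
            continue
        partner = tuple(_FLIP[s] for s in t)
        ordered.append(t)
        seen.add(t)
        if partner != t:
            ordered.append(partner)  # complementary pattern sits adjacent
            seen.add(partner)
    ordered.append(("S", "S", "S"))
    return tuple(ordered)


#: Canonical enumeration of all 27 triples; index i corresponds to id "r{i+1:02d}".
RESPONSE_TYPE_ORDER: tuple[tuple[str, str, str], ...] = _canonical_order()
_TRIPLE_TO_INDEX = {t: i for i, t in enumerate(RESPONSE_TYPE_ORDER)}

#: Id of the all-sustained triple (always last in the canonical order).
SUSTAINED_TYPE_ID = f"r{len(RESPONSE_TYPE_ORDER):02d}"


def response_type_id(states: tuple[str, str, str]) -> str:
    """Canonical id ("r01".."r27") of a {U, D, S} triple."""
    states = tuple(states)
    if states not in _TRIPLE_TO_INDEX:
        raise ValueError(f"not a valid state triple: {states}")
    return f"r{_TRIPLE_TO_INDEX[states] + 1:02d}"


# ---------------------------------------------------------------------------
# annotation hierarchy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnnotationHierarchy:
    """Rooted category tree with gene attachments and a top-level partition.

    ``nodes`` holds every path prefix plus the root (empty string);
    ``gene_to_node`` attaches each annotated gene at its deepest stated
    node; ``partition`` labels each gene "SOM-interaction" when its
    top-level path element matches one of ``som_top_labels`` (default
    {"SOM"}), "metabolism" otherwise.
    """

    nodes: frozenset[str]
    gene_to_node: dict[str, str]
    partition: dict[str, str]
    delimiter: str = "/"

    def genes(self) -> list[str]:
        return list(self.gene_to_node)

    def som_genes(self) -> set[str]:
        return {g for g, p in self.partition.items() if p == "SOM-interaction"}


def build_hierarchy(
    annotations: pd.DataFrame,
    delimiter: str = "/",
    som_top_labels: frozenset[str] = frozenset({"SOM"}),
) -> AnnotationHierarchy:
    """Build the annotation hierarchy from a (gene_id, category_path) table.

    Rows with path "null" (or empty) are treated as unannotated and
    skipped. A gene listed with two different non-null paths is an error
    naming the gene.
    """
    required = {"gene_id", "category_path"}
    if not required <= set(annotations.columns):
        raise ValueError(f"annotation table needs columns {sorted(required)}")
    gene_to_node: dict[str, str] = {}
    partition: dict[str, str] = {}
    nodes: set[str] = {""}
    conflicts: list[str] = []
    for gene, path in zip(annotations["gene_id"], annotations["category_path"]):
        if path is None or (isinstance(path, float) and np.isnan(path)):
            continue
        path = str(path).strip()
        if path in ("", "null"):
            continue
        if gene in gene_to_node and gene_to_node[gene] != path:
            conflicts.append(str(gene))
            continue
        gene_to_node[gene] = path
        parts = path.split(delimiter)
        for i in range(1, len(parts) + 1):
            nodes.add(delimiter.join(parts[:i]))
        top = parts[0]
        partition[gene] = ("SOM-interaction" if top in som_top_labels
                           else "metabolism")
    if conflicts:
        raise AnnotationError(
            f"genes with conflicting annotation paths: {sorted(set(conflicts))}")
    return AnnotationHierarchy(
        nodes=frozenset(nodes), gene_to_node=dict(gene_to_node),
        partition=dict(partition), delimiter=delimiter)


# ---------------------------------------------------------------------------
# annotation-guided clustering
# ---------------------------------------------------------------------------

def cluster_genes(
    profiles: pd.DataFrame,
    hierarchy: AnnotationHierarchy,
    corr_threshold: float = DEFAULT_CORR_THRESHOLD,
) -> pd.DataFrame:
    """Single-linkage correlation clustering within annotation nodes.

    ``profiles`` is a genes x time-points frame of mean log2 expression
    (time-DEGs only). Within each deepest annotation node, genes whose
    profile Pearson correlation chains above ``corr_threshold`` join one
    cluster; zero-variance profiles are uncorrelated with everything and
    form singletons. Returns a frame with ``node`` and ``cluster_id``
    per gene.
    """
    unannotated = [g for g in profiles.index if g not in hierarchy.gene_to_node]
    if unannotated:
        raise AnnotationError(
            f"clustering input contains unannotated genes: {unannotated[:5]}")
    records = []
    by_node: dict[str, list[str]] = {}
    for g in profiles.index:
        by_node.setdefault(hierarchy.gene_to_node[g], []).append(g)
    for node, genes in by_node.items():
        if len(genes) == 1:
            records.append((genes[0], node, f"{node}#1"))
            continue
        X = profiles.loc[genes].to_numpy(dtype=float)
        sd = X.std(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            corr = np.corrcoef(X)
        corr[~np.isfinite(corr)] = 0.0        # zero-variance profiles
        corr[sd == 0, :] = 0.0
        corr[:, sd == 0] = 0.0
        np.fill_diagonal(corr, 1.0)
        dist = np.clip(1.0 - corr, 0.0, 2.0)
        Z = linkage(squareform(dist, checks=False), method="single")
        labels = fcluster(Z, t=1.0 - corr_threshold, criterion="distance")
        for g, lab in zip(genes, labels):
            records.append((g, node, f"{node}#{lab}"))
    out = pd.DataFrame(records, columns=["gene_id", "node", "cluster_id"])
    return out.set_index("gene_id").loc[profiles.index]


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def _state_from_stats(lfc: np.ndarray, p_adj: np.ndarray,
                      fold_threshold: float, alpha: float) -> np.ndarray:
    log2_thr = np.log2(fold_threshold)
    states = np.full(lfc.shape, "S", dtype="<U1")
    states[(lfc >= log2_thr) & (p_adj < alpha)] = "U"
    states[(lfc <= -log2_thr) & (p_adj < alpha)] = "D"
    return states


def classify_profiles(
    pairwise: dict[str, pd.DataFrame],
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
    adjust: bool = True,
) -> pd.DataFrame:
    """Map genes to response types from the three consecutive contrasts.

    ``pairwise`` maps each transition label in :data:`TRANSITIONS` to a
    :func:`~ecmsom.expression.test_pairwise` result frame (columns
    ``lfc``, ``p`` and ``p_adj``) over a common gene index. Returns per
    gene the state at each transition, the canonical ``response_type``
    id, and a ``changing`` flag (False for the all-sustained triple).
    ``adjust=False`` thresholds raw instead of BH-adjusted p-values
    (useful for calibration studies where multiplicity handling would
    make the state calls degenerate).
    """
    missing = [t for t in TRANSITIONS if t not in pairwise]
    if missing:
        raise ValueError(f"missing contrasts for transitions: {missing}")
    genes = pairwise[TRANSITIONS[0]].index
    p_col = "p_adj" if adjust else "p"
    cols = {}
    for t in TRANSITIONS:
        frame = pairwise[t]
        if not frame.index.equals(genes):
            frame = frame.loc[genes]
        cols[t] = _state_from_stats(
            frame["lfc"].to_numpy(), frame[p_col].to_numpy(),
            fold_threshold, alpha)
    triples = list(zip(cols["ND"], cols["CD"], cols["pCD"]))
    ids = [response_type_id(t) for t in triples]
    out = pd.DataFrame({
        "ND": cols["ND"], "CD": cols["CD"], "pCD": cols["pCD"],
        "response_type": ids,
        "changing": [t != ("S", "S", "S") for t in triples]}, index=genes)
    out.index.name = "gene_id"
    return out


def classify_response(
    lfcs: dict[str, float],
    p_adjs: dict[str, float],
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
) -> tuple[tuple[str, str, str], str]:
    """Single-gene convenience wrapper: returns (state triple, type id)."""
    states = tuple(
        _state_from_stats(np.array([lfcs[t]]), np.array([p_adjs[t]]),
                          fold_threshold, alpha)[0]
        for t in TRANSITIONS)
    return states, response_type_id(states)


def count_types(profiles: pd.DataFrame) -> tuple[pd.Series, int]:
    """Per-type gene counts among changing genes and the distinct-type count.

    The all-sustained type is excluded: the counts partition the changing
    genes and the distinct count is the number of nonempty changing types.
    """
    changing = profiles[profiles["changing"]]
    counts = changing["response_type"].value_counts().sort_index()
    return counts, int((counts > 0).sum())


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PermutationResult:
    """Per-type permutation significance of SOM-interaction gene counts."""

    table: pd.DataFrame       # per type: observed, null mean/q95, p_emp
    B: int
    seed: int
    statistic: str


def _som_counts_by_type(
    counts_df, meta, gene_is_som: np.ndarray, time_labels: list[str],
    factors, fold_threshold, alpha, min_dispersion, pseudocount, statistic,
    adjust: bool = True,
) -> np.ndarray:
    pairwise = {}
    for trans, (tx, tref) in zip(TRANSITIONS,
                                 zip(time_labels[1:], time_labels[:-1])):
        pairwise[trans] = test_pairwise(
            counts_df, meta, tx, tref, min_dispersion=min_dispersion,
            pseudocount=pseudocount, factors=factors)
    prof = classify_profiles(pairwise, fold_threshold, alpha, adjust=adjust)
    type_idx = np.array([_TRIPLE_TO_INDEX[t] for t in
                         zip(prof["ND"], prof["CD"], prof["pCD"])])
    n_changing = len(RESPONSE_TYPE_ORDER) - 1
    som_counts = np.bincount(type_idx[gene_is_som],
                             minlength=len(RESPONSE_TYPE_ORDER))[:n_changing]
    if statistic == "som_count":
        return som_counts.astype(float)
    # hypergeometric alternative: -log10 enrichment p of SOM genes per type
    all_counts = np.bincount(type_idx, minlength=len(RESPONSE_TYPE_ORDER))[:n_changing]
    M = len(type_idx)
    n_som = int(gene_is_som.sum())
    with np.errstate(divide="ignore"):
        stat = -np.log10(np.clip(
            hypergeom.sf(som_counts - 1, M, n_som, np.maximum(all_counts, 1)),
            1e-300, 1.0))
    if type_sizes_out is not None:
        type_sizes_out.append(all_counts)
    return stat


def permutation_test(
    counts,
    meta: pd.DataFrame,
    hierarchy: AnnotationHierarchy,
    B: int = 999,
    seed: int = 0,
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
    min_dispersion: float = DEFAULT_MIN_DISPERSION,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    statistic: str = "som_count",
    adjust: bool = True,
) -> PermutationResult:
    """Permutation test of time points for response-type significance.

    For each of ``B`` permutations the sample time-point labels are
    shuffled (group sizes, and hence the replicate structure of the
    design, are preserved), the pairwise-DE -> classify -> count chain is
    re-run on the annotated genes, and the per-type count of
    SOM-interaction genes (or, with ``statistic="hypergeom"``, the
    hypergeometric enrichment score) is recorded. The empirical p-value
    of a type is ``(1 + #{null >= observed}) / (B + 1)``.
    """
    if B < 19:
        raise ValueError("B must be >= 19 for usable p-value resolution")
    if statistic not in ("som_count", "hypergeom"):
        raise ValueError("statistic must be 'som_count' or 'hypergeom'")
    counts_df = counts if isinstance(counts, pd.DataFrame) else pd.DataFrame(counts)
    annotated = [g for g in counts_df.index if g in hierarchy.gene_to_node]
    if not annotated:
        raise AnnotationError("no annotated genes in the count matrix")
    sub = counts_df.loc[annotated]
    gene_is_som = np.array(
        [hierarchy.partition[g] == "SOM-interaction" for g in annotated])
    factors = size_factors(counts_df)      # label-independent, computed once
    time_labels = sorted(meta["time_point"].unique())

    observed = _som_counts_by_type(
        sub, meta, gene_is_som, time_labels, factors,
        fold_threshold, alpha, min_dispersion, pseudocount, statistic,
        adjust=adjust)

    rng = np.random.default_rng(seed)
    labels = meta["time_point"].to_numpy()
    n_changing = len(RESPONSE_TYPE_ORDER) - 1
    null_ge = np.zeros(n_changing)
    null_sum = np.zeros(n_changing)
    null_draws = np.empty((B, n_changing))
    for b in range(B):
        perm_meta = meta.copy()
        perm_meta["time_point"] = rng.permutation(labels)
        draw = _som_counts_by_type(
            sub, perm_meta, gene_is_som, time_labels, factors,
            fold_threshold, alpha, min_dispersion, pseudocount, statistic,
            adjust=adjust)
        null_draws[b] = draw
        null_ge += draw >= observed
        null_sum += draw
    p_emp = (1.0 + null_ge) / (B + 1.0)
    type_ids = [f"r{i + 1:02d}" for i in range(n_changing)]
    table = pd.DataFrame({
        "pattern": ["".join(t) for t in RESPONSE_TYPE_ORDER[:n_changing]],
        "observed": observed,
        "null_mean": null_sum / B,
        "null_q95": np.quantile(null_draws, 0.95, axis=0),
        "p_emp": p_emp,
        "observed_nonzero": observed > 0,
    }, index=pd.Index(type_ids, name="response_type"))
    return PermutationResult(table=table, B=B, seed=seed, statistic=statistic)
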