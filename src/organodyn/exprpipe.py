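"""Cross-species temporal transcriptome analysis.

Implements the full bulk RNA-seq time-course comparison between two species
sharing an ortholog gene list: TPM normalization, QC projections (PCA,
Pearson correlation maps), a three-stage gene filter (abundance, temporal
dynamics, replicate consistency), fuzzy c-means soft clustering of z-scored
temporal profiles with replicates kept separate, consistency-based cluster
assignment, detection of genes whose temporal cluster shifts between
species, per-cluster hypergeometric gene-set enrichment, and the weighted
arc graph of species-exclusive term shifts.

Cluster labels are shared across species because all profiles — both
species, every replicate — are pooled into a single clustering run; a
"shift" is then simply a gene assigned to different clusters in the two
species, and a "robust shift" a gene whose replicates never co-occur in any
cluster across species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import hypergeom
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: sentinel label for genes whose replicates landed in pairwise-distinct clusters
DROPPED = -1

__all__ = [
    "DROPPED",
    "CountMatrix",
    "TpmMatrix",
    "TemporalProfileSet",
    "FilterReport",
    "FuzzyClusterModel",
    "ClusterAssignment",
    "ShiftSet",
    "TermShiftGraph",
    "compute_tpm",
    "zscale_profiles",
    "most_variable_genes",
    "correlation_map",
    "pca_projection",
    "filter_abundance",
    "filter_dynamic",
    "filter_replicate_consistency",
    "fuzzy_cmeans",
    "assign_clusters",
    "detect_shifts",
    "enrich_terms",
    "term_shift_graph",
    "intersect_tf",
    "run_pipeline",
    "read_gmt",
    "write_gmt",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class CountMatrix:
    """Gene-level counts for both species with sample metadata.

    ``counts``: genes x samples non-negative integers. ``sample_meta``: one
    row per sample column with ``species`` (label), ``day`` (numeric) and
    ``replicate`` (label/int). ``gene_length``: bp per gene, used for TPM.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame
    gene_length: pd.Series

    def __post_init__(self) -> None:
        if not self.counts.index.is_unique:
            raise ValueError("gene ids must be unique")
        missing = set(self.counts.columns) - set(self.sample_meta.index)
        if missing:
            raise ValueError(f"sample_meta missing samples: {sorted(missing)}")
        for col in ("species", "day", "replicate"):
            if col not in self.sample_meta.columns:
                raise ValueError(f"sample_meta lacks required column {col!r}")
        lengths = self.gene_length.reindex(self.counts.index)
        if lengths.isna().any() or (lengths <= 0).any():
            raise ValueError("every gene needs a positive length")
        self.gene_length = lengths.astype(float)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def species(self) -> list[str]:
        return sorted(self.sample_meta["species"].unique())

    @property
    def days(self) -> list:
        return sorted(self.sample_meta["day"].unique())


@dataclass
class TpmMatrix:
    """Within-sample TPM normalization and its log2(TPM+1) transform."""

    tpm: pd.DataFrame
    log2_tpm: pd.DataFrame
    sample_meta: pd.DataFrame


@dataclass
class TemporalProfileSet:
    """z-scored temporal profiles, one row per (gene, species, replicate).

    ``z`` columns are timepoints in increasing day order. For each row,
    z_i = (x_i - mu) / sigma with x_i the log2(TPM+1) at timepoint i and
    mu, sigma the mean and sample SD across timepoints. Rows that were
    constant across timepoints are stored as all-zero and flagged in
    ``constant`` (they carry no temporal pattern and are excluded from
    clustering).
    """

    z: pd.DataFrame  # MultiIndex (gene, species, replicate) x timepoints
    constant: pd.Series  # bool per row
    level: str = "replicate"

    @property
    def timepoints(self) -> list:
        return list(self.z.columns)

    def clusterable(self) -> pd.DataFrame:
        """Rows usable for clustering (non-constant)."""
        return self.z.loc[~self.constant]


@dataclass(frozen=True)
class FilterReport:
    stage: str
    genes_in: tuple[str, ...]
    genes_out: tuple[str, ...]

    def __post_init__(self) -> None:
        if not set(self.genes_out) <= set(self.genes_in):
            raise ValueError("filter output must be a subset of its input")

    @property
    def n_in(self) -> int:
        return len(self.genes_in)

    @property
    def n_out(self) -> int:
        return len(self.genes_out)


@dataclass
class FuzzyClusterModel:
    k: int
    m: float
    centroids: np.ndarray  # k x T
    membership: pd.DataFrame  # profiles x k, rows sum to 1
    objective_history: tuple[float, ...]
    n_iter: int
    converged: bool
    seed: int

    def hard_labels(self) -> pd.Series:
        """Argmax-membership cluster per profile; ties to the lowest index."""
        u = self.membership.to_numpy()
        labels = u.argmax(axis=1)  # argmax takes the first (lowest) on ties
        n_ties = int((u == u.max(axis=1, keepdims=True)).sum(axis=1).max() > 1)
        if n_ties:
            logger.info("membership ties present; broken toward lowest cluster index")
        return pd.Series(labels, index=self.membership.index, name="cluster")


@dataclass
class ClusterAssignment:
    """Per (gene, species): replicate hard labels and the majority cluster.

    ``assigned`` holds the label shared by at least two replicates, or
    ``DROPPED`` when the replicate labels are pairwise distinct.
    """

    table: pd.DataFrame  # index (gene, species); columns: labels (tuple), assigned

    def assigned_matrix(self) -> pd.DataFrame:
        """Genes x species matrix of assigned labels (DROPPED included)."""
        return self.table["assigned"].unstack("species")

    def genes_dropped(self) -> frozenset[str]:
        drop = self.table[self.table["assigned"] == DROPPED]
        return frozenset(drop.index.get_level_values("gene"))

    def genes_assigned_both(self) -> frozenset[str]:
        mat = self.assigned_matrix()
        ok = (mat != DROPPED).all(axis=1) & mat.notna().all(axis=1)
        return frozenset(mat.index[ok])


@dataclass(frozen=True)
class ShiftSet:
    robust_shift: frozenset[str]
    assigned_shift: frozenset[str]
    evaluated: frozenset[str]  # genes assigned in both species


@dataclass
class TermShiftGraph:
    """Weighted arc graph of species-exclusive enrichment shifts.

    An arc (a, b) collects the terms enriched in species A exclusively at
    cluster a and in species B exclusively at cluster b; its weight is the
    number of such terms. Terms enriched at the same cluster in both species
    are recorded as shared, not as arcs.
    """

    graph: nx.DiGraph
    shared: dict[str, tuple[int, ...]]  # term -> clusters shared by both species
    species_a: str
    species_b: str

    def heaviest_arc(self) -> tuple[int, int, int] | None:
        """(cluster_a, cluster_b, weight) of the heaviest arc; ties to lowest pair."""
        if self.graph.number_of_edges() == 0:
            return None
        best = max(
            self.graph.edges(data="weight"),
            key=lambda e: (e[2], -e[0], -e[1]),
        )
        return int(best[0]), int(best[1]), int(best[2])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "cluster_a": a,
                "cluster_b": b,
                "weight": d["weight"],
                "terms": ";".join(d["terms"]),
            }
            for a, b, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["cluster_a", "cluster_b", "weight", "terms"])


# ---------------------------------------------------------------------------
# normalization and QC


def compute_tpm(cm: CountMatrix) -> TpmMatrix:
    """Transcripts-per-million within each sample, plus log2(TPM+1).

    TPM[g, s] = 1e6 * (count/length) / sum_g(count/length).
    """
    rate = cm.counts.div(cm.gene_length, axis=0)
    colsum = rate.sum(axis=0)
    dead = colsum[colsum == 0]
    if len(dead):
        raise ZeroDivisionError(
            f"sample(s) with all-zero counts: {', '.join(map(str, dead.index))}"
        )
    tpm = rate.div(colsum, axis=1) * 1e6
    return TpmMatrix(tpm=tpm, log2_tpm=np.log2(tpm + 1.0), sample_meta=cm.sample_meta)


def _profile_table(tm: TpmMatrix, level: str) -> pd.DataFrame:
    """log2 TPM rearranged to (gene, species, replicate) x timepoint."""
    meta = tm.sample_meta
    days = sorted(meta["day"].unique())
    frames = {}
    if level == "replicate":
        groups = meta.groupby(["species", "replicate"], sort=True)
        for (sp, rep), sub in groups:
            ordered = sub.sort_values("day")
            if list(ordered["day"]) != days:
                raise ValueError(
                    f"replicate ({sp}, {rep}) does not cover every timepoint"
                )
            block = tm.log2_tpm[ordered.index]
            block.columns = days
            frames[(sp, rep)] = block
    elif level == "mean":
        for sp, sub in meta.groupby("species", sort=True):
            cols = {}
            for day, daysub in sub.groupby("day", sort=True):
                cols[day] = tm.log2_tpm[daysub.index].mean(axis=1)
            frames[(sp, "mean")] = pd.DataFrame(cols)[days]
    else:
        raise ValueError(f"unknown level {level!r}")
    out = pd.concat(frames, names=["species", "replicate"], axis=0)
    # reorder index to (gene, species, replicate)
    out.index = out.index.reorder_levels([2, 0, 1])
    out.index.names = ["gene", "species", "replicate"]
    return out.sort_index()


def zscale_profiles(
    tm: TpmMatrix, level: Literal["replicate", "mean"] = "replicate"
) -> TemporalProfileSet:
    """z-score each temporal profile: (x_i - mu) / sigma across timepoints.

    ``level='replicate'`` scales each (gene, species, replicate) profile;
    ``level='mean'`` first averages log2 TPM over replicates per timepoint
    and scales the per-species mean profile. Sample SD (ddof=1) is used.
    Constant profiles become all-zero and are flagged, never NaN.
    """
    prof = _profile_table(tm, level)
    if prof.shape[1] < 2:
        raise ValueError("z-scaling needs at least 2 timepoints")
    x = prof.to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    constant = (sd[:, 0] == 0.0)
    sd_safe = np.where(sd == 0.0, 1.0, sd)
    z = (x - mu) / sd_safe
    z[constant, :] = 0.0
    return TemporalProfileSet(
        z=pd.DataFrame(z, index=prof.index, columns=prof.columns),
        constant=pd.Series(constant, index=prof.index, name="constant"),
        level=level,
    )


def most_variable_genes(tm: TpmMatrix, n: int) -> list[str]:
    """Top-``n`` genes by variance of log2 TPM across all samples.

    Ties are broken by gene id order for determinism.
    """
    if n > tm.log2_tpm.shape[0]:
        raise ValueError("n exceeds the number of genes")
    var = tm.log2_tpm.var(axis=1, ddof=1)
    order = sorted(var.index, key=lambda g: (-var[g], str(g)))
    return list(order[:n])


def correlation_map(matrix: pd.DataFrame) -> pd.DataFrame:
    """Sample x sample Pearson correlation of a genes x samples matrix.

    Zero-variance columns yield NaN correlations, which are reported rather
    than silently imputed; the diagonal is forced to exactly 1.
    """
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 genes to correlate samples")
    flat = matrix.std(axis=0, ddof=1) == 0
    if flat.any():
        logger.warning(
            "zero-variance sample column(s): %s; correlations set to NaN",
            ", ".join(map(str, matrix.columns[flat])),
        )
    corr = matrix.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    corr.values[np.ix_(flat.to_numpy(), ~flat.to_numpy())] = np.nan
    corr.values[np.ix_(~flat.to_numpy(), flat.to_numpy())] = np.nan
    return corr


def pca_projection(
    matrix: pd.DataFrame, n_components: int
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples from a genes x samples matrix.

    Returns per-sample scores and explained-variance fractions
    (non-increasing, summing to at most 1).
    """
    X = matrix.T.to_numpy(dtype=float)  # samples x genes
    n_components = int(n_components)
    if n_components > min(X.shape):
        raise ValueError("n_components exceeds min(samples, genes)")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return (
        pd.DataFrame(scores, index=matrix.columns, columns=cols),
        pca.explained_variance_ratio_,
    )


# ---------------------------------------------------------------------------
# the three gene filters (applied in order: abundance -> dynamic -> consistency)


def filter_abundance(tm: TpmMatrix, threshold: float = 10.0) -> FilterReport:
    """Keep genes expressed above ``threshold`` TPM at >=1 timepoint in every
    replicate of both species."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    meta = tm.sample_meta
    keep = pd.Series(True, index=tm.tpm.index)
    for (_sp, _rep), sub in meta.groupby(["species", "replicate"], sort=True):
        keep &= (tm.tpm[sub.index] > threshold).any(axis=1)
    genes_in = tuple(tm.tpm.index)
    return FilterReport("abundance", genes_in, tuple(tm.tpm.index[keep]))


def filter_dynamic(
    tm: TpmMatrix,
    fc: float = 1.5,
    genes: Sequence[str] | None = None,
    level: Literal["mean", "any_replicate"] = "mean",
    pseudocount: float = 1.0,
) -> FilterReport:
    """Keep genes with a > ``fc`` fold-change between some pair of timepoints
    in at least one species.

    The per-timepoint summary is the replicate-mean TPM (default) or any
    single replicate; a pseudocount stabilizes ratios near zero.
    """
    if fc <= 1:
        raise ValueError("fold-change threshold must exceed 1")
    meta = tm.sample_meta
    tpm = tm.tpm if genes is None else tm.tpm.loc[list(genes)]
    keep = pd.Series(False, index=tpm.index)
    for _sp, sub in meta.groupby("species", sort=True):
        if level == "mean":
            per_day = pd.DataFrame(
                {
                    day: tpm[dsub.index].mean(axis=1)
                    for day, dsub in sub.groupby("day", sort=True)
                }
            )
            ratio = (per_day.max(axis=1) + pseudocount) / (
                per_day.min(axis=1) + pseudocount
            )
            keep |= ratio > fc
        elif level == "any_replicate":
            for _rep, rsub in sub.groupby("replicate", sort=True):
                ordered = rsub.sort_values("day")
                block = tpm[ordered.index]
                ratio = (block.max(axis=1) + pseudocount) / (
                    block.min(axis=1) + pseudocount
                )
                keep |= ratio > fc
        else:
            raise ValueError(f"unknown level {level!r}")
    return FilterReport("dynamic", tuple(tpm.index), tuple(tpm.index[keep]))


def replicate_discordance(profiles: TemporalProfileSet) -> pd.DataFrame:
    """Summed squared z-score differences across replicate pairs.

    For each gene and species, D = sum over timepoints of sum over unordered
    replicate pairs (r, r') of (z_r - z_r')^2. Small D means replicates agree
    on the temporal shape.
    """
    z = profiles.z
    rows = []
    for (gene, sp), sub in z.groupby(level=["gene", "species"], sort=True):
        arr = sub.to_numpy()
        r = arr.shape[0]
        d = 0.0
        for i in range(r):
            for j in range(i + 1, r):
                d += float(((arr[i] - arr[j]) ** 2).sum())
        rows.append({"gene": gene, "species": sp, "D": d})
    return pd.DataFrame(rows).set_index(["gene", "species"])


def filter_replicate_consistency(
    profiles: TemporalProfileSet, cutoff: float = 6.0
) -> FilterReport:
    """Remove genes whose replicate z-profiles disagree (D > cutoff) in
    either species."""
    n_reps = profiles.z.groupby(level=["gene", "species"]).size()
    if (n_reps < 2).any():
        raise ValueError("replicate-consistency filter needs >=2 replicates")
    disc = replicate_discordance(profiles)
    bad = disc[disc["D"] > cutoff].index.get_level_values("gene").unique()
    genes_in = tuple(profiles.z.index.get_level_values("gene").unique())
    genes_out = tuple(g for g in genes_in if g not in set(bad))
    return FilterReport("replicate_consistency", genes_in, genes_out)


# ---------------------------------------------------------------------------
# soft clustering


def fuzzy_cmeans(
    profiles: TemporalProfileSet | pd.DataFrame,
    k: int,
    m: float = 2.0,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 300,
) -> FuzzyClusterModel:
    """Fuzzy c-means over pooled temporal profiles (both species, all reps).

    Standard fixed-point iteration: membership
    u_ij = 1 / sum_l (d_ij / d_il)^(2/(m-1)) and centroid
    c_j = sum_i u_ij^m x_i / sum_i u_ij^m, stopped when the largest centroid
    coordinate shift drops below ``tol``. A profile coincident with a
    centroid takes membership 1 there (the limit case). Centroids are
    initialized from a seeded k-means, which makes the run deterministic and
    starts the fixed point near the density modes.
    """
    if isinstance(profiles, TemporalProfileSet):
        X_df = profiles.clusterable()
    else:
        X_df = profiles
    X = X_df.to_numpy(dtype=float)
    n = X.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if m <= 1:
        raise ValueError("fuzzifier m must exceed 1")
    if n < k:
        raise ValueError(f"{n} profiles cannot support k={k} clusters")

    km = KMeans(n_clusters=k, n_init=10, random_state=int(seed))
    km.fit(X)
    C = km.cluster_centers_.astype(float)

    exponent = 2.0 / (m - 1.0)
    history: list[float] = []
    converged = False
    u = np.full((n, k), 1.0 / k)
    for it in range(1, max_iter + 1):
        d2 = cdist(X, C, metric="sqeuclidean")
        zero = d2 <= 1e-300
        with np.errstate(divide="ignore"):
            w = d2 ** (-exponent / 2.0)  # = d^{-2/(m-1)}
        w[zero.any(axis=1)] = 0.0
        w[zero] = 1.0  # coincident profile -> one-hot membership
        u = w / w.sum(axis=1, keepdims=True)
        um = u**m
        history.append(float((um * d2).sum()))
        C_new = (um.T @ X) / um.sum(axis=0)[:, None]
        shift = float(np.abs(C_new - C).max())
        C = C_new
        if shift < tol:
            converged = True
            break
    membership = pd.DataFrame(u, index=X_df.index, columns=range(k))
    return FuzzyClusterModel(
        k=k,
        m=m,
        centroids=C,
        membership=membership,
        objective_history=tuple(history),
        n_iter=len(history),
        converged=converged,
        seed=int(seed),
    )


def assign_clusters(model: FuzzyClusterModel) -> ClusterAssignment:
    """Per-species consistency assignment from hardened memberships.

    Each replicate profile is hardened to its argmax cluster; a gene-species
    pair is assigned to the label held by at least two replicates, or
    DROPPED when all replicate labels are pairwise distinct (with ties among
    equally supported labels broken toward the lowest label).
    """
    hard = model.hard_labels()
    rows = []
    for (gene, sp), sub in hard.groupby(level=["gene", "species"], sort=True):
        labels = tuple(int(v) for v in sub.to_numpy())
        counts = pd.Series(labels).value_counts()
        if counts.max() >= 2:
            best = counts[counts == counts.max()].index.min()
            assigned = int(best)
        else:
            assigned = DROPPED
        rows.append(
            {"gene": gene, "species": sp, "labels": labels, "assigned": assigned}
        )
    table = pd.DataFrame(rows).set_index(["gene", "species"])
    return ClusterAssignment(table)


def detect_shifts(assign: ClusterAssignment) -> ShiftSet:
    """Genes whose temporal cluster differs between the two species.

    ``assigned_shift``: majority labels differ. ``robust_shift``: the two
    species' replicate label sets are disjoint — no replicate of one species
    ever co-clusters with a replicate of the other. Only genes assigned
    (not DROPPED) in both species are evaluated.
    """
    species = sorted(assign.table.index.get_level_values("species").unique())
    if len(species) != 2:
        raise ValueError(f"shift detection needs exactly 2 species, got {species}")
    sp_a, sp_b = species
    evaluated = assign.genes_assigned_both()
    robust, assigned = set(), set()
    for gene in evaluated:
        row_a = assign.table.loc[(gene, sp_a)]
        row_b = assign.table.loc[(gene, sp_b)]
        if row_a["assigned"] != row_b["assigned"]:
            assigned.add(gene)
        if not (set(row_a["labels"]) & set(row_b["labels"])):
            robust.add(gene)
    return ShiftSet(
        robust_shift=frozenset(robust),
        assigned_shift=frozenset(assigned),
        evaluated=frozenset(evaluated),
    )


# ---------------------------------------------------------------------------
# enrichment and the term-shift graph


def enrich_terms(
    cluster_genes: Iterable[str],
    term_map: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    alpha: float = 0.05,
    correction: Literal["bh", "none"] = "bh",
) -> pd.DataFrame:
    """Hypergeometric over-representation of each term in a gene cluster.

    For a term with K genes in a universe of N, a cluster of n genes and an
    overlap of k, the upper-tail p-value is P(X >= k) for
    X ~ Hypergeom(N, K, n). Adjustment is Benjamini-Hochberg across the
    terms of this call (one call per species x cluster); ``enriched`` marks
    adjusted_p < alpha. Terms with no gene in the universe are skipped.
    """
    universe = frozenset(universe)
    cluster = frozenset(cluster_genes)
    if not cluster <= universe:
        raise ValueError("cluster genes must be a subset of the universe")
    N, n = len(universe), len(cluster)
    rows = []
    for term in sorted(term_map):
        term_in_universe = frozenset(term_map[term]) & universe
        K = len(term_in_universe)
        if K == 0:
            logger.info("term %r has no genes in the universe; skipped", term)
            continue
        k = len(term_in_universe & cluster)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {"term": term, "k": k, "n": n, "K": K, "N": N, "p": min(p, 1.0)}
        )
    df = pd.DataFrame(rows, columns=["term", "k", "n", "K", "N", "p"])
    if len(df) == 0:
        df["adjusted_p"] = pd.Series(dtype=float)
        df["enriched"] = pd.Series(dtype=bool)
        return df
    if correction == "bh":
        df["adjusted_p"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    elif correction == "none":
        df["adjusted_p"] = df["p"]
    else:
        raise ValueError(f"unknown correction {correction!r}")
    df["enriched"] = df["adjusted_p"] < alpha
    return df


def enrich_clusters(
    assign: ClusterAssignment,
    term_map: Mapping[str, Iterable[str]],
    universe: Iterable[str] | None = None,
    alpha: float = 0.05,
    correction: Literal["bh", "none"] = "bh",
) -> pd.DataFrame:
    """Enrichment of every (species, cluster) gene set; tidy long table.

    The default background universe is the clustered gene list (genes
    assigned in that species); pass an explicit universe to widen it.
    """
    mat = assign.assigned_matrix()
    frames = []
    for sp in mat.columns:
        assigned_sp = mat[sp][(mat[sp].notna()) & (mat[sp] != DROPPED)]
        uni = frozenset(universe) if universe is not None else frozenset(assigned_sp.index)
        for cluster in sorted(assigned_sp.unique()):
            genes = frozenset(assigned_sp.index[assigned_sp == cluster]) & uni
            res = enrich_terms(genes, term_map, uni, alpha=alpha, correction=correction)
            res.insert(0, "cluster", int(cluster))
            res.insert(0, "species", sp)
            frames.append(res)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def term_shift_graph(
    enrich_a: pd.DataFrame,
    enrich_b: pd.DataFrame,
    species_a: str = "A",
    species_b: str = "B",
) -> TermShiftGraph:
    """Weighted arc graph of terms enriched in different clusters per species.

    Each input is the enrichment table of one species with columns
    ``cluster``, ``term`` and ``enriched``. For every term, arcs run from
    each cluster where it is enriched exclusively in species A to each
    cluster where it is enriched exclusively in species B; clusters enriched
    in both species are recorded as shared.
    """
    def _hits(df: pd.DataFrame) -> dict[str, set[int]]:
        hits: dict[str, set[int]] = {}
        if len(df) == 0:
            return hits
        for _, row in df[df["enriched"]].iterrows():
            hits.setdefault(row["term"], set()).add(int(row["cluster"]))
        return hits

    hits_a, hits_b = _hits(enrich_a), _hits(enrich_b)
    g = nx.DiGraph()
    shared: dict[str, tuple[int, ...]] = {}
    for term in sorted(set(hits_a) | set(hits_b)):
        ca, cb = hits_a.get(term, set()), hits_b.get(term, set())
        both = ca & cb
        if both:
            shared[term] = tuple(sorted(both))
        for a in sorted(ca - cb):
            for b in sorted(cb - ca):
                if g.has_edge(a, b):
                    g[a][b]["terms"].append(term)
                    g[a][b]["weight"] += 1
                else:
                    g.add_edge(a, b, terms=[term], weight=1)
    return TermShiftGraph(graph=g, shared=shared, species_a=species_a, species_b=species_b)


def intersect_tf(
    shift_genes: Iterable[str], term_genes: Iterable[str], tf_list: Iterable[str]
) -> list[str]:
    """Shifted genes annotated to given terms that are transcription factors.

    Returns the triple intersection in deterministic (sorted) order.
    """
    return sorted(frozenset(shift_genes) & frozenset(term_genes) & frozenset(tf_list))


# ---------------------------------------------------------------------------
# end-to-end pipeline


@dataclass
class PipelineResult:
    tpm: TpmMatrix
    reports: tuple[FilterReport, ...]
    profiles: TemporalProfileSet
    model: FuzzyClusterModel
    assignment: ClusterAssignment
    shifts: ShiftSet
    enrichment: pd.DataFrame
    graph: TermShiftGraph
    provenance: dict


def run_pipeline(
    cm: CountMatrix,
    term_map: Mapping[str, Iterable[str]] | None = None,
    k: int = 10,
    m: float = 2.0,
    seed: int = 0,
    tpm_threshold: float = 10.0,
    fc_threshold: float = 1.5,
    consistency_cutoff: float = 6.0,
    alpha: float = 0.05,
    correction: Literal["bh", "none"] = "bh",
) -> PipelineResult:
    """Run the full comparison: TPM -> filters -> clustering -> shifts -> terms.

    Filter order is abundance, temporal dynamics, then (after z-scaling)
    replicate consistency; clustering pools both species' replicate profiles
    of the surviving genes so cluster labels are directly comparable across
    species.
    """
    tpm = compute_tpm(cm)
    rep1 = filter_abundance(tpm, tpm_threshold)
    rep2 = filter_dynamic(tpm, fc_threshold, genes=rep1.genes_out)
    sub_tpm = TpmMatrix(
        tpm=tpm.tpm.loc[list(rep2.genes_out)],
        log2_tpm=tpm.log2_tpm.loc[list(rep2.genes_out)],
        sample_meta=tpm.sample_meta,
    )
    profiles = zscale_profiles(sub_tpm, level="replicate")
    rep3 = filter_replicate_consistency(profiles, consistency_cutoff)
    survivors = list(rep3.genes_out)
    kept = profiles.z.index.get_level_values("gene").isin(set(survivors))
    profiles = TemporalProfileSet(
        z=profiles.z.loc[kept],
        constant=profiles.constant.loc[kept],
        level=profiles.level,
    )
    model = fuzzy_cmeans(profiles, k=k, m=m, seed=seed)
    assignment = assign_clusters(model)
    shifts = detect_shifts(assignment)
    # species order follows first appearance in the sample sheet, so the
    # term-shift arcs run from the first listed species to the second
    species = list(dict.fromkeys(cm.sample_meta["species"]))
    if term_map is not None:
        enrichment = enrich_clusters(
            assignment, term_map, alpha=alpha, correction=correction
        )
        graph = term_shift_graph(
            enrichment[enrichment["species"] == species[0]],
            enrichment[enrichment["species"] == species[1]],
            species_a=species[0],
            species_b=species[1],
        )
    else:
        enrichment = pd.DataFrame()
        graph = TermShiftGraph(nx.DiGraph(), {}, species[0], species[1])
    provenance = {
        "k": k,
        "m": m,
        "seed": seed,
        "tpm_threshold": tpm_threshold,
        "fc_threshold": fc_threshold,
        "consistency_cutoff": consistency_cutoff,
        "alpha": alpha,
        "correction": correction,
        "n_genes_in": len(cm.genes),
        "n_genes_clustered": len(survivors),
    }
    return PipelineResult(
        tpm=tpm,
        reports=(rep1, rep2, rep3),
        profiles=profiles,
        model=model,
        assignment=assignment,
        shifts=shifts,
        enrichment=enrichment,
        graph=graph,
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# file formats


def read_gmt(path: str | Path) -> dict[str, frozenset[str]]:
    """Read a GMT gene-set file (term, description, genes...)."""
    term_map: dict[str, frozenset[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        term_map[parts[0]] = frozenset(g for g in parts[2:] if g)
    return term_map


def write_gmt(term_map: Mapping[str, Iterable[str]], path: str | Path) -> None:
    lines = [
        "\t".join([term, "na", *sorted(term_map[term])]) for term in sorted(term_map)
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_counts(
    counts_tsv: str | Path, meta_tsv: str | Path, lengths_tsv: str | Path
) -> CountMatrix:
    """Assemble a CountMatrix from counts, sample-metadata and gene-length TSVs."""
    counts = pd.read_csv(counts_tsv, sep="\t", index_col=0)
    meta = pd.read_csv(meta_tsv, sep="\t", index_col=0)
    lengths = pd.read_csv(lengths_tsv, sep="\t", index_col=0).iloc[:, 0]
    return CountMatrix(counts=counts, sample_meta=meta, gene_length=lengths)
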