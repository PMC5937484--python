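"""Alpha/beta diversity, ordination, and fraction-aware community summaries.

Covers the statistical layer of the pipeline: rarefied MOTU richness at a
fixed depth (hypergeometric closed form or seeded resampling), Shannon
diversity, Bray-Curtis dissimilarity on fourth-root-transformed relative
read frequencies, Mantel matrix correlation, multi-factor PERMANOVA on a
nested site / community(site) / fraction design, non-metric MDS by SMACOF
with isotonic regression, Venn partitions of MOTUs across the three size
fractions, and read/MOTU percentages per ecological size category.

Conventions: Shannon uses natural log on un-rarefied relative abundances
(rarefaction is applied to richness only); "fourth root" is x**(1/4); all
permutation tests report p = (1 + #{perm stat >= observed}) / (n_perm + 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import pdist, squareform
from scipy.special import gammaln
from skbio.stats.distance import DistanceMatrix

from .motu import MOTUTable
from .taxassign import Assignment
from .taxonomy import TaxonomyTree


class DiversityError(ValueError):
    pass


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

def rarefied_richness(counts: Sequence[int] | np.ndarray, depth: int = 19_000,
                      mode: str = "closed_form", n_resample: int = 100,
                      seed: int = 0) -> float:
    """Expected MOTU richness in a random subsample of ``depth`` reads.

    Closed form: E[S] = sum_i [1 - C(N - N_i, depth) / C(N, depth)], the
    expectation of the number of MOTUs with at least one read in a
    without-replacement subsample.  ``mode="resample"`` instead averages the
    observed richness of seeded subsamples.  Samples with fewer than
    ``depth`` reads raise (callers flag and exclude them).
    """
    c = np.asarray([x for x in counts if x > 0], dtype=np.int64)
    N = int(c.sum())
    if depth > N:
        raise DiversityError(f"depth {depth} exceeds sample total {N}")
    if depth <= 0:
        raise DiversityError("depth must be positive")
    if mode == "closed_form":
        def log_choose(n: np.ndarray | int, k: int) -> np.ndarray:
            return gammaln(np.asarray(n) + 1) - gammaln(k + 1) - gammaln(np.asarray(n) - k + 1)
        with np.errstate(invalid="ignore"):
            log_miss = log_choose(N - c, depth) - log_choose(N, depth)
        miss = np.where(N - c >= depth, np.exp(log_miss), 0.0)
        return float((1.0 - miss).sum())
    if mode == "resample":
        rng = np.random.default_rng(seed)
        reads = np.repeat(np.arange(c.size), c)
        vals = []
        for _ in range(n_resample):
            sub = rng.choice(reads, size=depth, replace=False)
            vals.append(np.unique(sub).size)
        return float(np.mean(vals))
    raise DiversityError(f"unknown mode {mode!r}")


def shannon(counts: Sequence[int] | np.ndarray, base: float = math.e) -> float:
    """Shannon diversity H = -sum p_i log p_i over nonzero proportions."""
    c = np.asarray(counts, dtype=np.float64)
    c = c[c > 0]
    if c.size == 0:
        raise DiversityError("Shannon index of an all-zero sample")
    p = c / c.sum()
    return float(-(p * np.log(p)).sum() / math.log(base))


def alpha_diversity_table(table: MOTUTable, depth: int = 19_000,
                          mode: str = "closed_form", seed: int = 0
                          ) -> pd.DataFrame:
    """Per-sample rarefied richness and Shannon index; samples below the
    rarefaction depth are flagged (richness NaN) rather than dropped."""
    rows = []
    for sid in table.sample_ids:
        c = table.counts[sid].to_numpy()
        total = int(c.sum())
        if total >= depth and total > 0:
            rich = rarefied_richness(c, depth, mode=mode, seed=seed)
            flagged = False
        else:
            rich, flagged = float("nan"), True
        rows.append({"sample_id": sid, "total_reads": total,
                     "rarefied_richness": rich,
                     "shannon": shannon(c) if total > 0 else float("nan"),
                     "below_depth": flagged})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# beta diversity
# ---------------------------------------------------------------------------

def bray_curtis(table: MOTUTable | pd.DataFrame,
                transform: str = "fourth_root") -> DistanceMatrix:
    """Bray-Curtis dissimilarity between samples.

    Counts are converted to relative frequencies per sample, then
    fourth-root transformed (the severe transform that lets rare MOTUs
    weigh in) before BC(i,j) = sum|x_i - x_j| / sum(x_i + x_j).  Zero-total
    samples are excluded with a warning attribute.
    """
    counts = table.counts if isinstance(table, MOTUTable) else table
    totals = counts.sum(axis=0)
    keep = [s for s in counts.columns if totals[s] > 0]
    x = counts[keep].to_numpy(float)
    x = x / x.sum(axis=0, keepdims=True)
    if transform == "fourth_root":
        x = x ** 0.25
    elif transform != "none":
        raise DiversityError(f"unknown transform {transform!r}")
    d = pdist(x.T, metric="braycurtis")
    dm = DistanceMatrix(squareform(d), ids=keep)
    return dm


def mantel(d1: DistanceMatrix, d2: DistanceMatrix, n_perm: int = 999,
           seed: int = 0) -> tuple[float, float]:
    """Mantel correlation between two distance matrices over matching ids.

    r is the Pearson correlation of the off-diagonal upper triangles; p is
    the one-sided permutation p-value (rows/columns of the second matrix
    permuted jointly): (1 + #{perm r >= observed}) / (n_perm + 1).
    """
    if list(d1.ids) != list(d2.ids):
        if set(d1.ids) != set(d2.ids):
            raise DiversityError("distance matrices have different ids")
        d2 = d2.filter(d1.ids)
    m1, m2 = d1.data, d2.data
    n = m1.shape[0]
    iu = np.triu_indices(n, k=1)
    v1 = m1[iu]

    def corr(mat: np.ndarray) -> float:
        v2 = mat[iu]
        v1c, v2c = v1 - v1.mean(), v2 - v2.mean()
        denom = math.sqrt((v1c ** 2).sum() * (v2c ** 2).sum())
        if denom == 0:
            raise DiversityError("constant distance matrix in Mantel test")
        return float((v1c * v2c).sum() / denom)

    r_obs = corr(m2)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        if corr(m2[np.ix_(p, p)]) >= r_obs:
            hits += 1
    return r_obs, (1 + hits) / (n_perm + 1)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _group_ss(d2: np.ndarray, labels: np.ndarray) -> float:
    """Within-group sum of squares from a squared-distance matrix:
    sum over groups of (1/n_g) sum_{i<j in g} d2_ij."""
    ss = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        if idx.size < 2:
            continue
        sub = d2[np.ix_(idx, idx)]
        ss += sub[np.triu_indices(idx.size, k=1)].sum() / idx.size
    return ss


def permanova_oneway(dm: DistanceMatrix | np.ndarray,
                     grouping: Sequence, n_perm: int = 999,
                     seed: int = 0) -> tuple[float, float]:
    """One-way PERMANOVA pseudo-F and permutation p-value.

    F = (SS_among/(a-1)) / (SS_within/(N-a)); p by free permutation of the
    group labels.
    """
    d = dm.data if isinstance(dm, DistanceMatrix) else np.asarray(dm, float)
    d2 = d ** 2
    labels = np.asarray(pd.factorize(np.asarray(grouping))[0])
    n = d.shape[0]
    a = np.unique(labels).size
    if a < 2:
        raise DiversityError("grouping needs at least two levels")
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n

    def f_stat(lab: np.ndarray) -> float:
        ss_w = _group_ss(d2, lab)
        ss_a = ss_total - ss_w
        return (ss_a / (a - 1)) / (ss_w / (n - a))

    f_obs = f_stat(labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if f_stat(labels[rng.permutation(n)]) >= f_obs:
            hits += 1
    return f_obs, (1 + hits) / (n_perm + 1)


@dataclass
class DesignTable:
    """Per-sample factors for the nested design: site, community (nested in
    site), fraction, replicate."""

    frame: pd.DataFrame  # index: sample_id; columns: site, community, fraction, replicate

    def __post_init__(self):
        need = {"site", "community", "fraction", "replicate"}
        missing = need - set(self.frame.columns)
        if missing:
            raise DiversityError(f"design table lacks columns: {sorted(missing)}")
        comm_site = self.frame.groupby("community")["site"].nunique()
        if (comm_site > 1).any():
            bad = list(comm_site[comm_site > 1].index)
            raise DiversityError(f"communities span multiple sites: {bad}")

    @classmethod
    def from_samplesheet(cls, sheet) -> "DesignTable":
        rows = {e.sample_id: {"site": e.site, "community": e.community,
                              "fraction": e.fraction, "replicate": e.replicate}
                for e in sheet if not e.is_control}
        return cls(pd.DataFrame.from_dict(rows, orient="index"))


def permanova(dm: DistanceMatrix, design: DesignTable | pd.DataFrame,
              n_perm: int = 1_000, seed: int = 0) -> pd.DataFrame:
    """Multi-factor PERMANOVA for the nested design
    {site, fraction, site x fraction, community(site), sample(community)}.

    Sums of squares are partitioned from the squared distance matrix via the
    classical group-decomposition (SS among a grouping = SS total - within).
    Denominators follow the mixed-model expectations: site over
    community(site), community(site) over sample(community), fraction and
    site x fraction and sample(community) over the residual.  Permutation
    p-values permute observations freely for site, within site for fraction,
    site x fraction and community(site), and within community for
    sample(community).  Terms with fewer than two levels are skipped.
    """
    frame = design.frame if isinstance(design, DesignTable) else design
    ids = [s for s in dm.ids if s in frame.index]
    if len(ids) < len(dm.ids):
        dm = dm.filter(ids)
    frame = frame.loc[list(dm.ids)]
    d2 = dm.data ** 2
    n = d2.shape[0]
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n

    site = pd.factorize(frame["site"])[0]
    frac = pd.factorize(frame["fraction"])[0]
    comm = pd.factorize(frame["community"])[0]
    block = pd.factorize(frame["community"].astype(str) + "//"
                         + frame["replicate"].astype(str))[0]
    sf = pd.factorize(pd.Series(site).astype(str) + "//"
                      + pd.Series(frac).astype(str))[0]

    a = np.unique(site).size
    f = np.unique(frac).size
    c = np.unique(comm).size
    s = np.unique(block).size

    def partition(perm: np.ndarray) -> dict[str, float]:
        """Term sums of squares with observations re-ordered by ``perm``."""
        dd = d2[np.ix_(perm, perm)]
        A = {name: ss_total - _group_ss(dd, lab)
             for name, lab in (("site", site), ("fraction", frac),
                               ("sf", sf), ("comm", comm), ("block", block))}
        out = {
            "site": A["site"],
            "fraction": A["fraction"],
            "site_x_fraction": A["sf"] - A["site"] - A["fraction"],
            "community(site)": A["comm"] - A["site"],
            "sample(community)": A["block"] - A["comm"],
        }
        out["residual"] = ss_total - A["sf"] - A["block"] + A["site"]
        return out

    df = {
        "site": a - 1,
        "fraction": f - 1,
        "site_x_fraction": (a - 1) * (f - 1),
        "community(site)": c - a,
        "sample(community)": s - c,
    }
    df["residual"] = n - 1 - sum(df.values())
    denom_of = {
        "site": "community(site)",
        "fraction": "residual",
        "site_x_fraction": "residual",
        "community(site)": "sample(community)",
        "sample(community)": "residual",
    }
    strata_of = {
        "site": None,            # free permutation
        "fraction": site,        # within site
        "site_x_fraction": site,
        "community(site)": site,
        "sample(community)": comm,
    }

    identity = np.arange(n)
    ss_obs = partition(identity)

    def f_of(ss: Mapping[str, float], term: str) -> float:
        den = denom_of[term]
        if df[term] <= 0 or df[den] <= 0 or ss[den] <= 0:
            return float("nan")
        return (ss[term] / df[term]) / (ss[den] / df[den])

    rng = np.random.default_rng(seed)
    rows = []
    for term in ("site", "fraction", "site_x_fraction", "community(site)",
                 "sample(community)"):
        if df[term] <= 0:
            rows.append({"term": term, "df": df[term], "SS": ss_obs[term],
                         "MS": float("nan"), "pseudo_F": float("nan"),
                         "p_value": float("nan"), "note": "skipped: <2 levels"})
            continue
        f_obs = f_of(ss_obs, term)
        hits = 0
        strata = strata_of[term]
        for _ in range(n_perm):
            if strata is None:
                perm = rng.permutation(n)
            else:
                perm = identity.copy()
                for g in np.unique(strata):
                    idx = np.flatnonzero(strata == g)
                    perm[idx] = idx[rng.permutation(idx.size)]
            if f_of(partition(perm), term) >= f_obs:
                hits += 1
        rows.append({"term": term, "df": df[term], "SS": ss_obs[term],
                     "MS": ss_obs[term] / df[term], "pseudo_F": f_obs,
                     "p_value": (1 + hits) / (n_perm + 1), "note": ""})
    rows.append({"term": "residual", "df": df["residual"],
                 "SS": ss_obs["residual"],
                 "MS": ss_obs["residual"] / max(df["residual"], 1),
                 "pseudo_F": float("nan"), "p_value": float("nan"), "note": ""})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# non-metric MDS
# ---------------------------------------------------------------------------

@dataclass
class NMDSResult:
    coords: pd.DataFrame
    stress: float
    converged: bool
    degenerate: bool = False


def nmmds(dm: DistanceMatrix, k: int = 2, max_iter: int = 300,
          n_starts: int = 4, seed: int = 0, tol: float = 1e-9) -> NMDSResult:
    """Non-metric MDS: SMACOF majorization with isotonic regression.

    Minimizes Kruskal stress-1 = sqrt(sum (d - dhat)^2 / sum d^2) where dhat
    is the monotone regression of configuration distances on dissimilarity
    ranks.  The iteration keeps the best configuration seen, so the reported
    stress sequence is non-increasing; the best of ``n_starts`` random
    restarts (the first seeded by classical metric scaling) is returned.
    """
    d = dm.data
    n = d.shape[0]
    if n < k + 1:
        raise DiversityError(f"need at least {k + 1} points for {k} dimensions")
    iu = np.triu_indices(n, k=1)
    diss = d[iu]
    if np.allclose(diss, diss[0]):
        rng = np.random.default_rng(seed)
        coords = rng.standard_normal((n, k))
        return NMDSResult(pd.DataFrame(coords, index=list(dm.ids)),
                          _stress1(coords, diss, iu), False, degenerate=True)
    order = np.argsort(diss, kind="stable")
    rng = np.random.default_rng(seed)

    def classical_init() -> np.ndarray:
        J = np.eye(n) - np.ones((n, n)) / n
        B = -0.5 * J @ (d ** 2) @ J
        w, v = np.linalg.eigh(B)
        idx = np.argsort(w)[::-1][:k]
        return v[:, idx] * np.sqrt(np.maximum(w[idx], 0.0))

    best: tuple[float, np.ndarray, bool] | None = None
    for start in range(max(1, n_starts)):
        X = classical_init() if start == 0 else rng.standard_normal((n, k))
        prev = np.inf
        converged = False
        best_local: tuple[float, np.ndarray] | None = None
        for _ in range(max_iter):
            dist = pdist(X)
            dhat = np.empty_like(dist)
            dhat[order] = isotonic_regression(dist[order]).x
            denom = (dist ** 2).sum()
            stress = math.sqrt(((dist - dhat) ** 2).sum() / denom) if denom > 0 else np.inf
            if best_local is None or stress < best_local[0]:
                best_local = (stress, X.copy())
            if prev - stress < tol:
                converged = prev - stress > -tol
                break
            prev = stress
            # Guttman transform toward the disparities
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(dist > 0, dhat / dist, 0.0)
            R = squareform(ratio)
            B = -R
            np.fill_diagonal(B, R.sum(axis=1))
            X = B @ X / n
        st, Xb = best_local
        if best is None or st < best[0]:
            best = (st, Xb, converged)
    stress, X, converged = best
    coords = pd.DataFrame(X, index=list(dm.ids),
                          columns=[f"nmds{i + 1}" for i in range(k)])
    return NMDSResult(coords, stress, converged)


def _stress1(coords: np.ndarray, diss: np.ndarray, iu) -> float:
    dist = pdist(coords)
    denom = (dist ** 2).sum()
    return math.sqrt(((dist - diss) ** 2).sum() / denom) if denom > 0 else float("inf")


# ---------------------------------------------------------------------------
# Venn partitions and ecological categories
# ---------------------------------------------------------------------------

VENN_REGIONS = ("A", "B", "C", "AB", "AC", "BC", "ABC")


def venn_partition(table: MOTUTable, design: DesignTable | pd.DataFrame
                   ) -> dict[str, pd.DataFrame]:
    """Seven-region Venn partition of MOTUs across pooled size fractions.

    Per site, every MOTU detected in that site is classified by the set of
    fractions (A/B/C) it appears in (presence = pooled count > 0);
    percentages are over MOTUs detected in the site and sum to 100.
    """
    frame = design.frame if isinstance(design, DesignTable) else design
    ids = [s for s in table.sample_ids if s in frame.index]
    frame = frame.loc[ids]
    bad = set(frame["fraction"]) - {"A", "B", "C"}
    if bad:
        raise DiversityError(f"unknown fractions: {sorted(bad)}")
    out: dict[str, pd.DataFrame] = {}
    for site, sub in frame.groupby("site"):
        present: dict[str, set[str]] = {}
        for fr in ("A", "B", "C"):
            cols = list(sub.index[sub["fraction"] == fr])
            pooled = table.counts[cols].sum(axis=1) if cols else None
            present[fr] = set(pooled.index[pooled > 0]) if pooled is not None else set()
        regions = {r: 0 for r in VENN_REGIONS}
        detected = present["A"] | present["B"] | present["C"]
        for m in detected:
            pat = "".join(fr for fr in ("A", "B", "C") if m in present[fr])
            regions[pat] += 1
        total = len(detected)
        out[site] = pd.DataFrame({
            "region": list(VENN_REGIONS),
            "n_motus": [regions[r] for r in VENN_REGIONS],
            "pct": [100.0 * regions[r] / total if total else 0.0
                    for r in VENN_REGIONS],
        })
    return out


UNASSIGNED = "unassigned"


def resolve_category(taxid: int | None, tree: TaxonomyTree,
                     category_map: Mapping[int, str]) -> str:
    """Category of a taxon: nearest ancestor present in the map, else
    unassigned.  Assignments above phylum rank are unassigned by definition."""
    if taxid is None:
        return UNASSIGNED
    if tree.ancestor_at_rank(taxid, "phylum") is None:
        return UNASSIGNED
    for t in reversed(tree.lineage(taxid)):
        if t in category_map:
            return category_map[t]
    return UNASSIGNED


def category_summary(table: MOTUTable,
                     assignments: Mapping[str, Assignment],
                     category_map: Mapping[int, str], tree: TaxonomyTree,
                     design: DesignTable | pd.DataFrame) -> pd.DataFrame:
    """Read and MOTU percentages per ecological category, by community x
    fraction (replicates pooled).  Percentages sum to 100 per panel."""
    frame = design.frame if isinstance(design, DesignTable) else design
    ids = [s for s in table.sample_ids if s in frame.index]
    frame = frame.loc[ids]
    cat_of = {mid: resolve_category(
        assignments[mid].assigned_taxid if mid in assignments else None,
        tree, category_map) for mid in table.motu_ids}
    cats = sorted(set(cat_of.values()) | {UNASSIGNED})
    rows = []
    for (community, fraction), sub in frame.groupby(["community", "fraction"]):
        cols = list(sub.index)
        pooled = table.counts[cols].sum(axis=1)
        total_reads = int(pooled.sum())
        detected = pooled.index[pooled > 0]
        for cat in cats:
            mids = [m for m in pooled.index if cat_of[m] == cat]
            reads = int(pooled[mids].sum())
            motus = sum(1 for m in detected if cat_of[m] == cat)
            rows.append({
                "community": community, "fraction": fraction, "category": cat,
                "reads": reads,
                "pct_reads": 100.0 * reads / total_reads if total_reads else 0.0,
                "n_motus": motus,
                "pct_motus": 100.0 * motus / len(detected) if len(detected) else 0.0,
            })
    return pd.DataFrame(rows)
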