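"""Screen-level statistics: normalization, paired differential enrichment,
alpha-robust-rank-aggregation gene scoring, cross-screen intersection,
preranked enrichment scores and screen-design arithmetic.

The guide-level statistic is a paired log-ratio t: per replicate pair the
log2 ratio of (pseudocounted, size-factor normalized) treated over control
counts, then a one-sample t across replicates. Only its *ranking* feeds the
gene-level alpha-RRA step, which scores a gene by how improbably its guides'
normalized ranks concentrate in the top alpha fraction, via Beta
order-statistic CDFs, with a permutation p-value and BH FDR across genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

# -- normalization -----------------------------------------------------------

def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample size factors.

    Guides with a zero count in any sample are excluded from the
    geometric-mean reference; factor_s is the median over the remaining
    guides of counts[g, s] / geomean_g(counts).
    """
    mat = counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no guide has positive counts in every sample; "
            "consider a pseudocount before normalization"
        )
    logs = np.log(mat[positive])
    log_geomean = logs.mean(axis=1, keepdims=True)
    factors = np.median(np.exp(logs - log_geomean), axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Divide each sample's counts by its median-of-ratios size factor."""
    return counts / size_factors(counts)


def filter_zero_guides(counts: pd.DataFrame) -> pd.DataFrame:
    """Drop guides whose count is zero in every sample (order preserved)."""
    keep = (counts.to_numpy() != 0).any(axis=1)
    return counts.loc[keep]


# -- paired differential statistic -------------------------------------------

@dataclass
class ScreenDesign:
    """Paired control/treated design: one sample per condition per replicate."""

    frame: pd.DataFrame  # columns sample_id, condition, replicate

    def __post_init__(self) -> None:
        required = {"sample_id", "condition", "replicate"}
        if not required <= set(self.frame.columns):
            raise ValueError(f"design needs columns {sorted(required)}")
        conditions = set(self.frame["condition"])
        if conditions != {"control", "treated"}:
            raise ValueError(
                f"conditions must be exactly {{'control', 'treated'}}, got {sorted(conditions)}"
            )
        for rep, grp in self.frame.groupby("replicate"):
            if sorted(grp["condition"]) != ["control", "treated"]:
                raise ValueError(f"replicate {rep!r} lacks a control/treated pair")

    @property
    def pairs(self) -> list[tuple[str, str, str]]:
        """(replicate, control_sample, treated_sample) triples, replicate-sorted."""
        out = []
        for rep, grp in sorted(self.frame.groupby("replicate"), key=lambda kv: kv[0]):
            by_cond = dict(zip(grp["condition"], grp["sample_id"]))
            out.append((rep, by_cond["control"], by_cond["treated"]))
        return out

    @classmethod
    def from_sample_sheet(cls, sheet) -> "ScreenDesign":
        return cls(sheet.frame[["sample_id", "condition", "replicate"]].copy())


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (y > 0)."""
    from scipy.special import polygamma

    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(polygamma(2, x))
        x += dif
        if abs(dif) < 1e-8 * x:
            break
    return x


def _moderate_variances(s2: np.ndarray, dg: int) -> tuple[np.ndarray, float]:
    """Empirical-Bayes shrinkage of per-guide variances toward a common prior.

    Fits a scaled inverse-chi-square prior (d0, s0^2) to the observed
    variances by moment matching on log s^2 and returns the posterior
    variances (d0*s0^2 + dg*s2) / (d0 + dg) together with the prior df d0
    (inf = complete shrinkage). Guides with zero variance are excluded from
    the fit but still receive the shrunken value.
    """
    from scipy.special import digamma, polygamma

    pos = s2 > 0
    if pos.sum() < 2:
        return s2.copy(), 0.0  # nothing to fit; caller falls back
    z = np.log(s2[pos])
    evar = z.var(ddof=1) - float(polygamma(1, dg / 2.0))
    emean = z.mean() - float(digamma(dg / 2.0)) + math.log(dg / 2.0)
    if evar <= 0:
        d0 = math.inf
        s0_sq = math.exp(emean)
        return np.full_like(s2, s0_sq), d0
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_sq = math.exp(emean + float(digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    return (d0 * s0_sq + dg * s2) / (d0 + dg), d0


def paired_differential(
    norm_counts: pd.DataFrame,
    design: ScreenDesign,
    pseudocount: float = 0.5,
    moderate: bool = True,
) -> pd.DataFrame:
    """Per-guide paired log-ratio t statistic (treated vs control).

    For replicate i, d_i = log2(treated_i + c) - log2(control_i + c) on
    normalized counts; log2fc = mean(d) and stat = mean(d) / (sd/sqrt(m)).
    With ``moderate=True`` (default) the per-guide variance is shrunk toward
    a common prior fitted across all guides (empirical Bayes), and p is
    two-sided from t with m - 1 + d0 df; this borrows strength across guides
    the way negative-binomial screen tools share dispersion, and keeps the
    ranking from being dominated by guides with luckily tiny replicate
    variance at small m. With ``moderate=False`` the plain per-guide t with
    m - 1 df is used; guides with sd = 0 then get stat 0 / p 1 when the fold
    change is also 0, otherwise sd is clamped to the smallest positive sd
    observed.
    """
    pairs = design.pairs
    m = len(pairs)
    if m < 2:
        raise ValueError("need >= 2 replicate pairs for a variance estimate")
    d = np.column_stack(
        [
            np.log2(norm_counts[t].to_numpy(dtype=float) + pseudocount)
            - np.log2(norm_counts[c].to_numpy(dtype=float) + pseudocount)
            for _, c, t in pairs
        ]
    )
    log2fc = d.mean(axis=1)
    s2 = d.var(axis=1, ddof=1)
    dg = m - 1
    df: float = dg
    if moderate:
        s2_mod, d0 = _moderate_variances(s2, dg)
        if d0 > 0:
            s2 = s2_mod
            df = dg + d0
        else:
            moderate = False  # degenerate fixture; plain t below
    if not moderate:
        zero = s2 == 0
        if not zero.all():
            s2 = np.where(zero, s2[~zero].min(), s2)
    sd = np.sqrt(s2)
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = log2fc / (sd / math.sqrt(m))
    stat = np.where((sd == 0) & (log2fc == 0), 0.0, stat)
    stat = np.nan_to_num(stat, nan=0.0, posinf=np.inf, neginf=-np.inf)
    if math.isinf(df):
        p = 2.0 * stats.norm.sf(np.abs(stat))
    else:
        p = 2.0 * stats.t.sf(np.abs(stat), df=df)
    p = np.where(stat == 0, 1.0, p)
    return pd.DataFrame(
        {"log2fc": log2fc, "stat": stat, "p": np.clip(p, 0.0, 1.0)},
        index=norm_counts.index.copy(),
    )


def rank_guides(diff: pd.DataFrame, direction: str = "enriched") -> pd.DataFrame:
    """Normalized guide ranks from the test statistic.

    ``enriched`` sorts the statistic descending (most enriched guide gets
    rank 1), ``depleted`` ascending; ties break lexicographically by
    guide_id. Returns a frame with ``rank`` (1..n) and ``r`` = rank/n.
    """
    if direction not in ("enriched", "depleted"):
        raise ValueError("direction must be 'enriched' or 'depleted'")
    df = diff.reset_index()
    id_col = df.columns[0]
    ascending = direction == "depleted"
    df = df.sort_values(["stat", id_col], ascending=[ascending, True], kind="mergesort")
    df["rank"] = np.arange(1, len(df) + 1)
    df["r"] = df["rank"] / len(df)
    df["direction"] = direction
    return df.set_index(id_col)[["stat", "rank", "r", "direction"]]


def auto_alpha(diff: pd.DataFrame, direction: str = "enriched") -> float:
    """Default RRA cutoff: the fraction of guides on the tested side
    (positive statistic for enrichment, negative for depletion)."""
    stat = diff["stat"].to_numpy()
    frac = (stat > 0).mean() if direction == "enriched" else (stat < 0).mean()
    if frac == 0:
        raise ValueError(f"no guides with a {direction}-side statistic")
    return float(frac)


# -- alpha-RRA ---------------------------------------------------------------

def _rho_from_ranks(sorted_r: np.ndarray, alpha: float) -> tuple[float, int]:
    """Score one gene: min over selected order statistics of Beta CDFs.

    sorted_r are the gene's normalized ranks, ascending. Only ranks < alpha
    participate; rho = min_j BetaCDF(r_(j); j, k-j+1), or 1 if none qualify.
    """
    k = sorted_r.size
    sel = sorted_r < alpha
    k_sel = int(sel.sum())
    if k_sel == 0:
        return 1.0, 0
    j = np.arange(1, k_sel + 1)
    rho = stats.beta.cdf(sorted_r[:k_sel], j, k - j + 1).min()
    return float(rho), k_sel


def _null_rho(pool: np.ndarray, k: int, alpha: float, n_perm: int, rng) -> np.ndarray:
    """Null rho distribution for genes with k guides: draw k ranks per
    permutation (without replacement) from the pooled rank list."""
    null = np.empty(n_perm)
    j = np.arange(1, k + 1)
    for i in range(n_perm):
        r = np.sort(rng.choice(pool, size=k, replace=False))
        sel = r < alpha
        if not sel.any():
            null[i] = 1.0
        else:
            jj = j[: sel.sum()]
            null[i] = stats.beta.cdf(r[: sel.sum()], jj, k - jj + 1).min()
    return null


def alpha_rra(
    ranks: pd.DataFrame,
    guide_to_gene: dict[str, str],
    alpha: float,
    n_perm: int = 100,
    seed: int | None = None,
) -> pd.DataFrame:
    """Aggregate normalized guide ranks into per-gene RRA scores.

    Returns a frame indexed by gene with columns rho, p_perm, fdr, k, k_sel,
    sorted by (p_perm, rho, gene). The permutation p uses the add-one
    estimator (1 + #{null rho <= observed}) / (n_perm + 1), with one shared
    null distribution per guides-per-gene count k.
    """
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    r = ranks["r"]
    genes: dict[str, list[float]] = {}
    n_dropped = 0
    for guide, rv in r.items():
        gene = guide_to_gene.get(guide)
        if gene is None:
            n_dropped += 1
            continue
        genes.setdefault(gene, []).append(rv)
    if n_dropped:
        import logging

        logging.getLogger(__name__).warning(
            "%d ranked guides absent from the guide->gene map were dropped", n_dropped
        )
    if not genes:
        raise ValueError("no ranked guide maps to a gene")
    pool = r.to_numpy()
    rows = []
    null_by_k: dict[int, np.ndarray] = {}
    for gene in sorted(genes):
        rr = np.sort(np.asarray(genes[gene]))
        k = rr.size
        rho, k_sel = _rho_from_ranks(rr, alpha)
        if k not in null_by_k:
            null_by_k[k] = _null_rho(pool, k, alpha, n_perm, rng)
        p_perm = (1.0 + (null_by_k[k] <= rho).sum()) / (n_perm + 1.0)
        rows.append((gene, rho, p_perm, k, k_sel))
    out = pd.DataFrame(rows, columns=["gene", "rho", "p_perm", "k", "k_sel"]).set_index("gene")
    out["fdr"] = bh_adjust(out["p_perm"].to_numpy())
    out = out.sort_values(["p_perm", "rho"]).loc[
        :, ["rho", "p_perm", "fdr", "k", "k_sel"]
    ]
    return out


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


# -- cross-screen intersection -----------------------------------------------

def top_fraction_intersection(
    screen_a: pd.DataFrame, screen_b: pd.DataFrame, fraction: float = 0.25
) -> tuple[set[str], pd.DataFrame]:
    """Intersect the top fraction of two gene score tables.

    Each screen contributes its top floor(fraction * n) genes by ascending
    p_perm (ties by rho then gene). Returns the overlapping gene set and a
    frame of -log10 permutation p in both screens for those genes.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    if not set(screen_a.index) & set(screen_b.index):
        raise ValueError("gene universes do not overlap")

    def top(df: pd.DataFrame) -> list[str]:
        n = int(len(df) * fraction)
        ordered = df.reset_index().sort_values(
            ["p_perm", "rho", df.index.name or "gene"], kind="mergesort"
        )
        return ordered.iloc[:n, 0].tolist()

    overlap = set(top(screen_a)) & set(top(screen_b))
    genes = sorted(overlap)
    table = pd.DataFrame(
        {
            "neglog10_p_a": -np.log10(screen_a.loc[genes, "p_perm"]),
            "neglog10_p_b": -np.log10(screen_b.loc[genes, "p_perm"]),
        },
        index=pd.Index(genes, name="gene"),
    )
    return overlap, table


# -- preranked enrichment ----------------------------------------------------

@dataclass
class EnrichmentResult:
    es: float
    p_perm: float
    set_size: int


def _running_es(scores: np.ndarray, in_set: np.ndarray, weight: float) -> float:
    """Signed max deviation of the weighted Kolmogorov-Smirnov running sum."""
    n = scores.size
    n_set = int(in_set.sum())
    w = np.abs(scores) ** weight
    w_in = np.where(in_set, w, 0.0)
    total = w_in.sum()
    if total == 0:  # all in-set scores zero at weight > 0: fall back to hits
        w_in = in_set.astype(float)
        total = w_in.sum()
    step = w_in / total - (~in_set) / (n - n_set)
    walk = np.cumsum(step)
    return float(walk[np.argmax(np.abs(walk))])


def gsea_enrichment(
    scores: pd.Series,
    gene_set,
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int | None = None,
) -> EnrichmentResult:
    """Preranked enrichment score of a gene set in a scored gene list.

    Genes are ranked by score descending; the running sum increments by the
    normalized |score|^weight at set members and decrements by 1/(n - set
    size) elsewhere; ES is the signed maximum deviation. The permutation p
    shuffles set membership over the ranked list.
    """
    gene_set = set(gene_set)
    if not gene_set:
        raise ValueError("empty gene set")
    missing = gene_set - set(scores.index)
    if missing:
        raise ValueError(f"gene set members absent from ranking: {sorted(missing)[:5]}")
    if weight < 0:
        raise ValueError("weight must be >= 0")
    ordered = scores.sort_values(ascending=False, kind="mergesort")
    vals = ordered.to_numpy(dtype=float)
    in_set = ordered.index.isin(gene_set)
    n_set = int(in_set.sum())
    if n_set == len(ordered):
        raise ValueError("gene set equals the whole universe")
    es = _running_es(vals, in_set, weight)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = np.zeros(len(ordered), dtype=bool)
        perm[rng.choice(len(ordered), size=n_set, replace=False)] = True
        es_p = _running_es(vals, perm, weight)
        if (es >= 0 and es_p >= es) or (es < 0 and es_p <= es):
            hits += 1
    p_perm = (1.0 + hits) / (n_perm + 1.0)
    return EnrichmentResult(es=es, p_perm=p_perm, set_size=n_set)


# -- end-to-end gene scoring -------------------------------------------------

def score_screen(
    counts: pd.DataFrame,
    design: ScreenDesign,
    guide_to_gene: dict[str, str],
    direction: str = "enriched",
    alpha: float | None = None,
    n_perm: int = 100,
    seed: int | None = None,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Count matrix -> gene score table in one call.

    Drops all-zero guides, normalizes by median-of-ratios size factors,
    computes the paired log-ratio statistic, ranks guides in the requested
    direction and aggregates with alpha-RRA (alpha defaults to the fraction
    of guides on the tested side).
    """
    filtered = filter_zero_guides(counts)
    norm = normalize_counts(filtered)
    diff = paired_differential(norm, design, pseudocount=pseudocount)
    ranks = rank_guides(diff, direction=direction)
    if alpha is None:
        alpha = auto_alpha(diff, direction=direction)
    return alpha_rra(ranks, guide_to_gene, alpha=alpha, n_perm=n_perm, seed=seed)


# -- screen-design arithmetic ------------------------------------------------

def required_cells(coverage: float, library_size: int, surviving_fraction: float) -> int:
    """Cells needed for a target per-guide coverage of a pooled library.

    ceil(coverage x library_size / surviving_fraction), where the surviving
    fraction accounts for losses (e.g. infection at low MOI plus selection).
    """
    if coverage <= 0 or library_size <= 0:
        raise ValueError("coverage and library_size must be positive")
    if not (0 < surviving_fraction <= 1):
        raise ValueError("surviving_fraction must be in (0, 1]")
    return math.ceil(coverage * library_size / surviving_fraction)
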