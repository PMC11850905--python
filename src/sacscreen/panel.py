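"""Cell-line-panel association analytics.

Works over a :class:`PanelBundle`: a genes x lines expression matrix, a
drugs x lines response matrix (lower = more sensitive, the usual
log-fold-change viability convention), a per-line aneuploidy score and
per-drug class labels. Provides single-sample signature scores (ssGSEA),
top-vs-bottom-quartile t tests, linear-covariate partialization, and the
genome-wide gene x drug ranking-percentile profile for a target gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

logger = logging.getLogger(__name__)


@dataclass
class PanelBundle:
    """Expression, drug response, aneuploidy and drug classes on shared lines.

    Components are inner-joined on line identifiers at use; lines missing
    from any component are dropped for operations needing that component.
    """

    expression: pd.DataFrame  # genes x lines
    response: pd.DataFrame  # drugs x lines, lower = more sensitive
    aneuploidy: pd.Series | None = None  # per line
    drug_class: pd.Series | None = None  # per drug

    def __post_init__(self) -> None:
        if not set(self.expression.columns) & set(self.response.columns):
            raise ValueError("expression and response share no cell lines")
        for name, df in (("expression", self.expression), ("response", self.response)):
            if df.isna().all(axis=1).any():
                raise ValueError(f"{name} matrix has all-missing rows")

    @property
    def shared_lines(self) -> list[str]:
        lines = [c for c in self.expression.columns if c in set(self.response.columns)]
        return lines


@dataclass
class AssociationResult:
    delta: float  # top-quartile mean - bottom-quartile mean of response
    t_stat: float
    p: float
    n_top: int
    n_bottom: int


def ssgsea(expr_profile: pd.Series, gene_set, exponent: float = 0.25) -> float:
    """Single-sample enrichment score of a gene set in one expression profile.

    Genes are ranked by expression descending; the score is the sum over
    list positions of the difference between the weighted in-set ECDF
    (weights = rank score ** exponent, rank score n..1 from top) and the
    unweighted out-of-set ECDF. Depends on expression only through ranks, so
    it is invariant under strictly monotone transforms of the profile.
    """
    gene_set = set(gene_set)
    if not gene_set:
        raise ValueError("empty gene set")
    missing = gene_set - set(expr_profile.index)
    if missing:
        raise ValueError(f"gene set members absent from profile: {sorted(missing)[:5]}")
    n = len(expr_profile)
    if len(gene_set) == n:
        raise ValueError("gene set equals the whole universe; out-of-set ECDF undefined")
    ordered = expr_profile.reset_index()
    id_col, val_col = ordered.columns
    ordered = ordered.sort_values([val_col, id_col], ascending=[False, True], kind="mergesort")
    in_set = ordered[id_col].isin(gene_set).to_numpy()
    rank_score = np.arange(n, 0, -1, dtype=float)  # n for the top gene
    w = np.where(in_set, rank_score**exponent, 0.0)
    ecdf_in = np.cumsum(w) / w.sum()
    ecdf_out = np.cumsum(~in_set) / (n - len(gene_set))
    return float(np.sum(ecdf_in - ecdf_out))


def signature_scores(
    expression: pd.DataFrame, signatures: dict[str, list[str]], exponent: float = 0.25
) -> pd.DataFrame:
    """ssGSEA score per (signature, line) over an expression matrix."""
    rows = {
        name: {
            line: ssgsea(expression[line].dropna(), members, exponent=exponent)
            for line in expression.columns
        }
        for name, members in signatures.items()
    }
    return pd.DataFrame(rows).T


def quartile_groups(
    values: pd.Series, lower: float = 0.25, upper: float = 0.75
) -> tuple[pd.Index, pd.Index]:
    """Split lines into bottom-quartile and top-quartile groups.

    Bottom = values <= 25th percentile, top = values >= 75th percentile
    (boundary ties included; linear-interpolation quantiles). Needs >= 8
    non-missing values and a non-constant vector.
    """
    v = values.dropna()
    if len(v) < 8:
        raise ValueError(f"need >= 8 non-missing values, got {len(v)}")
    q_lo, q_hi = v.quantile([lower, upper], interpolation="linear")
    if q_lo == q_hi:
        raise ValueError("quartile boundaries coincide (near-constant vector)")
    bottom = v.index[v <= q_lo]
    top = v.index[v >= q_hi]
    return bottom, top


def _welch_or_pooled(
    x: np.ndarray, y: np.ndarray, equal_var: bool
) -> tuple[float, float]:
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0
    res = stats.ttest_ind(x, y, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def quartile_t_test(
    feature: pd.Series,
    response: pd.Series,
    equal_var: bool = False,
    min_group: int = 2,
) -> AssociationResult:
    """Compare response between the top and bottom quartiles of a feature.

    Welch t by default (``equal_var=True`` for the pooled flavor); delta and
    t are (top - bottom), so with the lower-is-more-sensitive response
    convention a negative delta means high feature values sensitize.
    """
    joined = pd.concat({"feature": feature, "response": response}, axis=1).dropna()
    bottom, top = quartile_groups(joined["feature"])
    x = joined.loc[top, "response"].to_numpy(dtype=float)
    y = joined.loc[bottom, "response"].to_numpy(dtype=float)
    if len(x) < min_group or len(y) < min_group:
        raise ValueError(f"quartile groups too small ({len(y)} bottom, {len(x)} top)")
    t, p = _welch_or_pooled(x, y, equal_var)
    return AssociationResult(
        delta=float(x.mean() - y.mean()), t_stat=t, p=p, n_top=len(x), n_bottom=len(y)
    )


def partial_out(response: pd.Series, covariate: pd.Series) -> pd.Series:
    """Remove a covariate's linear contribution from a response.

    Returns the residuals of an ordinary least-squares fit of response on
    the covariate (with intercept), indexed by the paired non-missing lines;
    residuals have zero mean and zero sample covariance with the covariate.
    """
    joined = pd.concat({"y": response, "x": covariate}, axis=1).dropna()
    if len(joined) < 3:
        raise ValueError("need >= 3 paired non-missing values")
    x = joined["x"].to_numpy(dtype=float)
    y = joined["y"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant")
    design = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return pd.Series(y - design @ beta, index=joined.index, name=response.name)


def aneuploidy_association(
    response: pd.Series,
    aneuploidy: pd.Series,
    covariate: pd.Series | None = None,
    equal_var: bool = False,
) -> tuple[AssociationResult, AssociationResult | None]:
    """Top-vs-bottom aneuploidy-quartile response test, before and after
    partializing out a covariate (e.g. a candidate mediator gene's expression)."""
    raw = quartile_t_test(aneuploidy, response, equal_var=equal_var)
    if covariate is None:
        return raw, None
    residual = partial_out(response, covariate)
    adjusted = quartile_t_test(aneuploidy, residual, equal_var=equal_var)
    return raw, adjusted


# -- genome-wide gene x drug profile -----------------------------------------

def _quartile_masks(expression: np.ndarray, gene_ids, lines) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene boolean masks over lines for bottom/top expression quartiles."""
    n_genes, _ = expression.shape
    q = np.nanquantile(expression, [0.25, 0.75], axis=1)
    bottom = expression <= q[0][:, None]
    top = expression >= q[1][:, None]
    bottom &= ~np.isnan(expression)
    top &= ~np.isnan(expression)
    return bottom, top


def _group_stats(resp: np.ndarray, mask: np.ndarray):
    """Mean/var/count of each drug's response within each gene's line group.

    resp: drugs x lines with NaN for missing; mask: genes x lines boolean.
    Returns (mean, var, n), each drugs x genes.
    """
    filled = np.nan_to_num(resp, nan=0.0)
    present = ~np.isnan(resp)
    maskf = mask.astype(float).T  # lines x genes
    n = present.astype(float) @ maskf
    s1 = filled @ maskf
    s2 = (filled**2) @ maskf
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = s1 / n
        var = (s2 - n * mean**2) / (n - 1)
    return mean, np.clip(var, 0.0, None), n


def gene_drug_associations(
    expression: pd.DataFrame,
    response: pd.DataFrame,
    min_group: int = 10,
    equal_var: bool = False,
) -> dict[str, pd.DataFrame]:
    """Vectorized top-vs-bottom-quartile t test for every (gene, drug) pair.

    Equivalent to calling :func:`quartile_t_test` per pair with pairwise
    deletion of missing values; pairs with fewer than ``min_group`` lines in
    either quartile get NaN. Returns drugs x genes frames 'delta', 't', 'p'.
    """
    lines = [c for c in expression.columns if c in set(response.columns)]
    if len(lines) < 8:
        raise ValueError("need >= 8 shared cell lines")
    expr = expression[lines].to_numpy(dtype=float)
    resp = response[lines].to_numpy(dtype=float)
    bottom, top = _quartile_masks(expr, expression.index, lines)
    m_t, v_t, n_t = _group_stats(resp, top)
    m_b, v_b, n_b = _group_stats(resp, bottom)
    ok = (n_t >= min_group) & (n_b >= min_group)
    with np.errstate(invalid="ignore", divide="ignore"):
        delta = m_t - m_b
        se2_t = v_t / n_t
        se2_b = v_b / n_b
        if equal_var:
            sp2 = ((n_t - 1) * v_t + (n_b - 1) * v_b) / (n_t + n_b - 2)
            se = np.sqrt(sp2 * (1 / n_t + 1 / n_b))
            df = n_t + n_b - 2
        else:
            se = np.sqrt(se2_t + se2_b)
            df = (se2_t + se2_b) ** 2 / (
                se2_t**2 / (n_t - 1) + se2_b**2 / (n_b - 1)
            )
        t = delta / se
        p = 2.0 * special.stdtr(df, -np.abs(t))
    degenerate = (se == 0) & (delta == 0)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    t = np.where(ok, t, np.nan)
    p = np.where(ok, p, np.nan)
    delta = np.where(ok, delta, np.nan)
    idx, cols = response.index, expression.index
    return {
        "delta": pd.DataFrame(delta, index=idx, columns=cols),
        "t": pd.DataFrame(t, index=idx, columns=cols),
        "p": pd.DataFrame(p, index=idx, columns=cols),
    }


def gene_drug_percentiles(
    panel: PanelBundle,
    target_gene: str,
    min_group: int = 10,
    equal_var: bool = False,
    high_is_significant: bool = True,
) -> pd.DataFrame:
    """Ranking percentile of a target gene's drug association, per drug.

    For every drug, every gene is tested (top vs bottom expression quartile
    response t test) and genes are ranked by ascending p (ties broken by
    gene identifier). The target's percentile is 100 * (1 - (rank - 1) / n),
    so 100 = the most significantly associated gene for that drug; set
    ``high_is_significant=False`` for the raw rank percentile instead.
    Drugs where the target test is invalid are dropped with a warning.
    """
    if target_gene not in panel.expression.index:
        raise ValueError(f"target gene {target_gene!r} not in the expression matrix")
    assoc = gene_drug_associations(
        panel.expression, panel.response, min_group=min_group, equal_var=equal_var
    )
    pmat = assoc["p"]
    rows = []
    gene_order = {g: i for i, g in enumerate(pmat.columns)}
    for drug in pmat.index:
        p_row = pmat.loc[drug]
        valid = p_row.dropna()
        if target_gene not in valid.index:
            logger.warning("drug %s: target test invalid (too few lines); dropped", drug)
            continue
        order = sorted(valid.index, key=lambda g: (valid[g], g))
        rank = order.index(target_gene) + 1
        pct = 100.0 * (1.0 - (rank - 1) / len(order))
        if not high_is_significant:
            pct = 100.0 - pct
        rows.append((drug, pct, valid[target_gene]))
    out = pd.DataFrame(rows, columns=["drug", "percentile", "p_target"]).set_index("drug")
    if panel.drug_class is not None:
        out["drug_class"] = panel.drug_class.reindex(out.index)
    return out


def compare_drug_classes(
    profile: pd.DataFrame, class_of_interest: str, equal_var: bool = False
) -> tuple[float, float]:
    """Two-sample t of ranking percentiles: one drug class against the rest."""
    if "drug_class" not in profile.columns:
        raise ValueError("profile has no drug_class column")
    in_class = profile["drug_class"] == class_of_interest
    x = profile.loc[in_class, "percentile"].to_numpy(dtype=float)
    y = profile.loc[~in_class, "percentile"].to_numpy(dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError(
            f"need >= 2 drugs in and out of class {class_of_interest!r} "
            f"(got {len(x)} in, {len(y)} out)"
        )
    return _welch_or_pooled(x, y, equal_var)


def spearman_association(scores: pd.Series, dependency: pd.Series) -> tuple[float, float]:
    """Spearman correlation between a per-line score and a continuous
    dependency/response vector (pairwise deletion). Thin utility."""
    joined = pd.concat({"s": scores, "d": dependency}, axis=1).dropna()
    if len(joined) < 3:
        raise ValueError("need >= 3 paired values")
    rho, p = stats.spearmanr(joined["s"], joined["d"])
    return float(rho), float(p)
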