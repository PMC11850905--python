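"""Mitotic-aberration severity scoring and the statistics around it.

Live-imaging mitotic events are scored on a 0-5 severity scale: 0 is a
correct segregation; 1-5 cover increasingly severe combinations of DNA
bridges, micronuclei, lagging chromosomes, metaphase misalignment,
cytokinesis failure and metaphase skipping. Events that fit no predefined
category carry a manual 1-5 score and are excluded from the main statistics
(but kept in exports). Per-condition severity distributions are compared
with Kruskal-Wallis tests (upper-tail chi-square p); metaphase durations
with t / one-way ANOVA.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

# Canonical category -> severity score. Score 3 vs 4 at the misalignment
# margin: the micronuclei clause is what promotes a misalignment-with-
# lagging/bridge event to score 4.
SEVERITY_TABLE: dict[str, int] = {
    "correct chromosomal segregation": 0,
    "dna bridge formation": 1,
    "micronucleus formation": 1,
    "chromosomal lagging": 1,
    "dna bridge/lagging with micronucleus formation": 2,
    "metaphase misalignment": 2,
    "metaphase misalignment with micronucleus formation": 3,
    "metaphase misalignment with chromosomal lagging/bridge formation": 3,
    "metaphase skipping": 4,
    "cytokinesis failure": 4,
    "metaphase misalignment with chromosomal lagging/bridge formation and micronuclei": 4,
    "metaphase skipping with dna bridging": 5,
    "metaphase skipping with micronucleus formation": 5,
}

# Common synonyms normalized onto the canonical tokens.
CATEGORY_ALIASES: dict[str, str] = {
    "correct segregation": "correct chromosomal segregation",
    "normal segregation": "correct chromosomal segregation",
    "dna bridge": "dna bridge formation",
    "micronucleus": "micronucleus formation",
    "micronuclei formation": "micronucleus formation",
    "lagging chromosome": "chromosomal lagging",
    "chromosome lagging": "chromosomal lagging",
    "misalignment": "metaphase misalignment",
    "metaphase skipping with dna bridge formation": "metaphase skipping with dna bridging",
    "metaphase misalignment with chromosomal lagging/bridge formation and emergence of micronuclei": (
        "metaphase misalignment with chromosomal lagging/bridge formation and micronuclei"
    ),
}

SCORES = range(6)


def canonical_category(category: str) -> str:
    token = " ".join(category.strip().lower().split())
    return CATEGORY_ALIASES.get(token, token)


def score_category(category: str, other_score: int | None = None) -> tuple[int, bool]:
    """Map an event category to (severity score 0-5, excluded flag).

    ``"other"`` events carry their manual 1-5 score and are flagged excluded
    (they do not enter the main severity statistics). Unknown categories
    raise with the accepted vocabulary listed.
    """
    token = canonical_category(category)
    if token == "other":
        if other_score is None or not 1 <= int(other_score) <= 5:
            raise ValueError("'other' events need a manual score in 1..5")
        return int(other_score), True
    if token not in SEVERITY_TABLE:
        raise ValueError(
            f"unknown category {category!r}; known categories: "
            + ", ".join(sorted(SEVERITY_TABLE))
            + ", other"
        )
    return SEVERITY_TABLE[token], False


def score_events(events: pd.DataFrame) -> pd.DataFrame:
    """Add ``score`` and ``excluded`` columns to an event table.

    Expects columns cell_id, condition, category and optionally other_score
    and duration_min.
    """
    required = {"cell_id", "condition", "category"}
    if not required <= set(events.columns):
        raise ValueError(f"event table needs columns {sorted(required)}")
    out = events.copy()
    scored = [
        score_category(
            row.category,
            None
            if "other_score" not in events.columns or pd.isna(getattr(row, "other_score", None))
            else int(row.other_score),
        )
        for row in out.itertuples()
    ]
    out["score"] = [s for s, _ in scored]
    out["excluded"] = [e for _, e in scored]
    return out


def severity_table(events: pd.DataFrame) -> pd.DataFrame:
    """Per-condition histogram over severity scores 0-5.

    'other' events are tallied only in the ``n_other_excluded`` column, so
    per condition: sum over score columns + n_other_excluded = n events.
    """
    if events.empty:
        raise ValueError("no events")
    scored = events if "score" in events.columns else score_events(events)
    rows = {}
    for condition, grp in scored.groupby("condition", sort=True):
        kept = grp.loc[~grp["excluded"], "score"]
        counts = kept.value_counts().reindex(SCORES, fill_value=0)
        rows[condition] = {**{int(s): int(counts[s]) for s in SCORES},
                           "n_other_excluded": int(grp["excluded"].sum())}
    return pd.DataFrame(rows).T.rename_axis("condition")


def severity_groups(events: pd.DataFrame) -> dict[str, np.ndarray]:
    """Per-condition severity score vectors ('other' events excluded)."""
    scored = events if "score" in events.columns else score_events(events)
    kept = scored.loc[~scored["excluded"]]
    return {c: g["score"].to_numpy() for c, g in kept.groupby("condition", sort=True)}


def kruskal_wallis(*score_groups) -> tuple[float, float]:
    """Kruskal-Wallis H (mid-rank ties, tie correction) and its upper-tail
    chi-square p with (groups - 1) df. All-identical observations give
    H = 0, p = 1."""
    groups = [np.asarray(g, dtype=float) for g in score_groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    if sum(len(g) for g in groups) < 3:
        raise ValueError("need >= 3 observations in total")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def compare_durations(*duration_groups) -> dict:
    """Compare metaphase durations: two-sided Welch t for two groups,
    one-way ANOVA for more. Returns {'test', 'stat', 'p', 'n'}."""
    groups = [np.asarray(g, dtype=float) for g in duration_groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups of >= 2 values each")
    if len(groups) == 2:
        x, y = groups
        if x.std(ddof=1) == 0 and y.std(ddof=1) == 0 and x.mean() == y.mean():
            stat, p = 0.0, 1.0
        else:
            res = stats.ttest_ind(x, y, equal_var=False)
            stat, p = float(res.statistic), float(res.pvalue)
        test = "welch_t"
    else:
        res = stats.f_oneway(*groups)
        stat, p = float(res.statistic), float(res.pvalue)
        test = "anova_f"
    return {"test": test, "stat": stat, "p": p, "n": [len(g) for g in groups]}


def densitometry_fold_change(
    target: dict[str, float],
    mitotic_marker: dict[str, float],
    loading_control: dict[str, float],
    treated_lane: str,
    control_lane: str,
) -> float:
    """Double-normalized western-blot fold change between two lanes.

    Per lane the target band is normalized to the mitotic marker, itself
    first normalized to the loading control: norm = target / (marker /
    control); the fold change is norm_treated / norm_control. All
    intensities must be positive.
    """
    def norm(lane: str) -> float:
        for name, d in (("target", target), ("mitotic_marker", mitotic_marker),
                        ("loading_control", loading_control)):
            if lane not in d:
                raise ValueError(f"lane {lane!r} missing from {name} intensities")
            if d[lane] <= 0:
                raise ValueError(f"non-positive {name} intensity in lane {lane!r}")
        return target[lane] / (mitotic_marker[lane] / loading_control[lane])

    return norm(treated_lane) / norm(control_lane)
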