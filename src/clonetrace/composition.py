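"""Clone-level fate composition: restricted vs mixed fractions, exclusive
fate classification, and UpSet-style intersection counts.

All operations work on a clone table (one row per cell with ``clone_id`` and
a state column).  A clone "contains" a state when it has at least
``presence_min`` cells of it — default 1 for composition summaries, whereas
the coupling statistic uses its own >= 2 rule.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd


def fate_table(clones: pd.DataFrame, state_col: str = "cell_type") -> pd.DataFrame:
    """Clone x state cell-count matrix (rows sum to clone sizes)."""
    tab = pd.crosstab(clones["clone_id"], clones[state_col])
    tab.index.name = "clone_id"
    return tab


def _presence(clones: pd.DataFrame, state_col: str, presence_min: int) -> pd.DataFrame:
    return fate_table(clones, state_col) >= presence_min


def clone_category_fractions(
    clones: pd.DataFrame,
    groups: Dict[str, Sequence[str]],
    anchor: Optional[str] = None,
    presence_min: int = 1,
    state_col: str = "cell_type",
) -> pd.DataFrame:
    """Fractions of anchor-containing clones that are restricted vs mixed.

    ``groups`` names disjoint sets of states (e.g. ``{"Ast": [...astrocyte
    subtypes...], "Exc_neuron": [...]}``).  Eligible clones are those
    containing the ``anchor`` group (default: the first group); each eligible
    clone falls in exactly one category — ``"<anchor> only"`` or
    ``"<anchor> + <others> mix"`` for the combination of other groups it also
    contains — so the fractions sum to 1.  This is the "Ast. only" vs
    "Exc. n. + Ast. mix" style of summary.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    all_states: list = []
    for sts in groups.values():
        all_states.extend(sts)
    if len(set(all_states)) != len(all_states):
        raise ValueError("groups must not overlap")
    if anchor is None:
        anchor = names[0]
    if anchor not in groups:
        raise ValueError(f"anchor {anchor!r} not among groups {names}")
    pres = _presence(clones, state_col, presence_min)
    group_pres = pd.DataFrame(
        {
            g: pres[[s for s in sts if s in pres.columns]].any(axis=1)
            for g, sts in groups.items()
        }
    )
    eligible = group_pres[group_pres[anchor]]
    others = [g for g in names if g != anchor]
    n = len(eligible)
    rows = []
    if n:
        combo = eligible[others].apply(
            lambda r: tuple(g for g in others if r[g]), axis=1
        )
        counts = combo.value_counts()
        for c, k in counts.items():
            name = f"{anchor} only" if not c else f"{anchor} + {' + '.join(c)} mix"
            rows.append((name, int(k), k / n))
    out = pd.DataFrame(rows, columns=["category", "n_clones", "fraction"])
    return out.sort_values("category", kind="mergesort").reset_index(drop=True)


def classify_clone_fates(
    clones: pd.DataFrame,
    precedence: List[Tuple[str, Sequence[str]]],
    fallback: str = "self_renewing",
    eligible_states: Optional[Sequence[str]] = None,
    eligible_min: int = 1,
    presence_min: int = 1,
    state_col: str = "cell_type",
) -> pd.DataFrame:
    """Exclusive fate category per clone.

    ``precedence`` is an ordered list of ``(category, defining states)``: a
    clone gets the first category whose defining states it contains (>=
    ``presence_min`` cells); clones containing none get ``fallback``.
    ``eligible_states`` optionally restricts the classified clones to those
    containing at least ``eligible_min`` cells of the listed states (e.g.
    clones containing a given progenitor subtype).  Categories are exclusive
    and exhaustive over the eligible clones, so their fractions sum to 1.
    """
    if not precedence:
        raise ValueError("precedence must name at least one category")
    tab = fate_table(clones, state_col)
    if eligible_states is not None:
        cols = [s for s in eligible_states if s in tab.columns]
        keep = tab[cols].sum(axis=1) >= eligible_min if cols else pd.Series(False, index=tab.index)
        tab = tab[keep]
    pres = tab >= presence_min
    cat = pd.Series(fallback, index=tab.index, dtype=object)
    assigned = pd.Series(False, index=tab.index)
    for name, states in precedence:
        cols = [s for s in states if s in pres.columns]
        hit = pres[cols].any(axis=1) if cols else pd.Series(False, index=pres.index)
        cat[hit & ~assigned] = name
        assigned |= hit
    return pd.DataFrame({"clone_id": tab.index, "fate_category": cat.to_numpy()})


def fate_fractions(categories: pd.DataFrame) -> pd.Series:
    """Category fractions from :func:`classify_clone_fates` output (sums to 1)."""
    if not len(categories):
        return pd.Series(dtype=float)
    return categories["fate_category"].value_counts(normalize=True).sort_index()


def upset_intersections(
    clones: pd.DataFrame,
    states: Sequence[str],
    presence_min: int = 1,
    state_col: str = "cell_type",
) -> pd.DataFrame:
    """Clone counts for every observed combination of present states.

    A clone is eligible when it contains at least one of ``states``; each
    eligible clone contributes to exactly one combination (its presence set),
    so the counts sum to the number of eligible clones.  Returns one row per
    observed combination with boolean indicator columns and ``n_clones``,
    sorted by decreasing count (ties by indicator pattern).
    """
    if not len(states):
        raise ValueError("need at least one state")
    pres = _presence(clones, state_col, presence_min)
    for s in states:
        if s not in pres.columns:
            pres[s] = False
    pres = pres[list(states)]
    pres = pres[pres.any(axis=1)]
    if not len(pres):
        out = pd.DataFrame(columns=[*states, "n_clones"])
        return out
    counts = pres.groupby(list(states)).size().rename("n_clones").reset_index()
    counts = counts.sort_values(
        ["n_clones", *states], ascending=[False] + [True] * len(states),
        kind="mergesort",
    ).reset_index(drop=True)
    return counts


# ---------------------------------------------------------------------------
# plots (optional outputs)

def plot_fate_fractions(fractions: pd.Series, path: Optional[str] = None, title: str = ""):
    """Stacked-bar plot of exclusive fate fractions."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(3, 4))
    bottom = 0.0
    for cat, frac in fractions.items():
        ax.bar([0], [frac], bottom=bottom, label=str(cat))
        bottom += frac
    ax.set_xticks([])
    ax.set_ylabel("fraction of clones")
    ax.set_title(title)
    ax.legend(fontsize=7)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig


def plot_upset(intersections: pd.DataFrame, path: Optional[str] = None):
    """Minimal UpSet-style plot: intersection bar chart + membership dots."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    states = [c for c in intersections.columns if c != "n_clones"]
    n = len(intersections)
    fig, (ax_bar, ax_dot) = plt.subplots(
        2, 1, figsize=(max(4, 0.5 * n + 2), 5), sharex=True,
        gridspec_kw={"height_ratios": [3, 1]},
    )
    ax_bar.bar(range(n), intersections["n_clones"], color="0.3")
    ax_bar.set_ylabel("clones")
    for xi in range(n):
        for yi, s in enumerate(states):
            on = bool(intersections.iloc[xi][s])
            ax_dot.plot(xi, yi, "o", color="0.1" if on else "0.85", ms=6)
    ax_dot.set_yticks(range(len(states)), states)
    ax_dot.set_xticks([])
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig
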