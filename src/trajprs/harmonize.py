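"""Percent-of-maximum harmonization of symptom checklist totals.

Repeated assessments in the cohort use abbreviated versions of a symptom
checklist whose items are rated 0-4, so the maximum attainable total is
``4 * n_items`` and differs across waves (6, 5, 17 and 17 items).  Totals are
put on a common scale by expressing each as a percentage of the maximum
attainable at that wave.  The transform is linear, so means, medians, IQRs and
any other linear or quantile summary commute with it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: items administered at each wave (0 = pre-deployment, 1 = post-deployment,
#: 2 and 3 = follow-ups); each item is rated 0-4.
WAVE_ITEM_COUNTS: tuple[int, ...] = (6, 5, 17, 17)

ITEM_MAX = 4  # per-item rating ceiling


def max_score(n_items: int) -> int:
    """Maximum attainable total for an instrument with ``n_items`` items."""
    if n_items <= 0:
        raise ValueError(f"n_items must be positive, got {n_items}")
    return ITEM_MAX * n_items


def harmonize_score(raw_total: float, n_items: int) -> float:
    """Express a raw checklist total as percent of the maximum possible score.

    Parameters
    ----------
    raw_total
        Sum of item ratings.  Non-integer values are accepted so that summary
        statistics of totals (means, IQRs) can be harmonized directly.
    n_items
        Number of items administered, each rated 0-4.

    Returns
    -------
    float
        ``100 * raw_total / (4 * n_items)``, in [0, 100].
    """
    m = max_score(n_items)
    if not np.isfinite(raw_total) or raw_total < 0 or raw_total > m:
        raise ValueError(
            f"raw_total {raw_total!r} outside the attainable range [0, {m}] "
            f"for a {n_items}-item instrument"
        )
    return 100.0 * raw_total / m


def harmonize_table(
    long: pd.DataFrame,
    item_counts: tuple[int, ...] = WAVE_ITEM_COUNTS,
) -> pd.DataFrame:
    """Fill the ``harmonized`` column of a long-format measurement table.

    Rows with ``observed == 0`` are left untouched (harmonized set to NaN for
    consistency if absent).  Each row's ``wave`` must index into
    ``item_counts``; the row's own ``n_items`` column, when present, must
    agree with the wave's instrument.
    """
    out = long.copy()
    waves = out["wave"].to_numpy()
    known = np.isin(waves, np.arange(len(item_counts)))
    if not known.all():
        bad = sorted(set(waves[~known].tolist()))
        raise ValueError(f"unknown wave id(s) {bad}; expected 0..{len(item_counts) - 1}")
    if len(out) == 0:
        out["harmonized"] = pd.Series(dtype=float)
        return out

    n_items = np.asarray(item_counts, dtype=float)[waves.astype(int)]
    if "n_items" in out.columns:
        obs_items = out["n_items"].to_numpy(dtype=float)
        if not np.array_equal(obs_items, n_items):
            raise ValueError("n_items column disagrees with the wave instrument map")
    observed = (
        out["observed"].to_numpy(dtype=bool)
        if "observed" in out.columns
        else np.ones(len(out), dtype=bool)
    )
    raw = out["raw_total"].to_numpy(dtype=float)
    maxima = ITEM_MAX * n_items
    valid = observed & np.isfinite(raw)
    if ((raw[valid] < 0) | (raw[valid] > maxima[valid])).any():
        raise ValueError("observed raw_total outside attainable range for its wave")
    harmonized = np.full(len(out), np.nan)
    harmonized[valid] = 100.0 * raw[valid] / maxima[valid]
    out["harmonized"] = harmonized
    return out
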