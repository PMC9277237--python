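"""Within-inflorescence seed-set pattern indices.

Seed set ``s`` is the number of seeds divided by twice the number of
florets — each floret carries two ovules, so ``s`` is the realised
fraction of ovule capacity and lives in [0, 0.5].

The *Seed Lateness Index* (SLI) is the median percentile position (0 =
basal, 100 = apical) of the seeded florets; with an even count of seeded
florets the *higher* of the two middle order statistics is taken. Because
florets open basally to apically, a low SLI means seeds concentrated in
early-opening florets.

SLI is inherently noisy when almost no floret seeded (s near 0) and pinned
near 50 when almost every floret seeded (s near 0.5), so regressions
involving SLI weight each inflorescence by the tent function
``w = 0.25 - |s - 0.25|``: maximal when half the florets seeded, zero at
both extremes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DomainValueError

__all__ = ["seed_set", "seed_weight", "sli_from_percentiles", "seed_summaries"]


def seed_set(n_seeds: int, n_florets: int) -> float:
    """Seed set s = n_seeds / (2 * n_florets).

    Reaches 0.5 when every floret sets one seed; values above 0.5 require
    double-seeded florets to outnumber empty ones, which field data show
    to be rare but which the formula permits (up to 1.0).
    """
    if n_florets < 1:
        raise DomainValueError("n_florets must be >= 1")
    if not 0 <= n_seeds <= 2 * n_florets:
        raise DomainValueError(
            f"n_seeds={n_seeds} inconsistent with {n_florets} two-ovule florets"
        )
    return n_seeds / (2 * n_florets)


def seed_weight(s: float) -> float:
    """Regression weight w = 0.25 - |s - 0.25|, clipped below at zero.

    The tent peaks at s = 0.25 (half the florets seeded, where SLI is
    best determined) and reaches zero at s = 0 and s = 0.5; the rare
    inflorescences beyond 0.5 also get zero weight.
    """
    s_arr = np.asarray(s, dtype=float)
    if np.any((s_arr < 0) | (s_arr > 1)):
        raise DomainValueError("seed set must lie in [0, 1]")
    w = np.maximum(0.0, 0.25 - np.abs(s_arr - 0.25))
    return float(w) if np.isscalar(s) or s_arr.ndim == 0 else w


def sli_from_percentiles(percentiles, n_seeds=None, seed_level: bool = False) -> float:
    """SLI of one inflorescence from its seeded-floret percentile positions.

    Parameters
    ----------
    percentiles
        Percentile positions of the seeded florets (one entry per seeded
        floret), each in [0, 100].
    n_seeds
        Seeds per listed floret; only used when ``seed_level`` is true.
    seed_level
        When true, a two-seed floret enters the median twice (a seed-level
        rather than floret-level median). Default is floret-level: the
        index is defined over floret locations.

    Returns NaN when no floret seeded — such inflorescences are excluded
    from lateness regressions rather than scored 0.
    """
    p = np.asarray(percentiles, dtype=float)
    if p.size and (np.any(p < 0) or np.any(p > 100)):
        raise DomainValueError("percentiles must lie in [0, 100]")
    if seed_level:
        if n_seeds is None:
            raise DomainValueError("seed_level SLI needs per-floret seed counts")
        p = np.repeat(p, np.asarray(n_seeds, dtype=int))
    if p.size == 0:
        return float("nan")
    p = np.sort(p)
    # median with the tie rule: even count -> the higher middle value
    return float(p[p.size // 2])


def seed_summaries(dissection: pd.DataFrame, seed_level: bool = False) -> pd.DataFrame:
    """Per-inflorescence seed indices from floret-level dissection records.

    Returns a DataFrame indexed by inflorescence_id with columns
    ``n_florets, n_seeds, s, sli, w``. ``sli`` is NaN for inflorescences
    with no seeded floret.
    """
    rows = []
    for infl, grp in dissection.groupby("inflorescence_id", sort=True):
        n_florets = int(grp["n_florets"].iloc[0])
        if len(grp) > n_florets:
            raise DomainValueError(
                f"{infl!r}: {len(grp)} floret records but n_florets={n_florets}"
            )
        n_seeds = int(grp["n_seeds"].sum())
        s = seed_set(n_seeds, n_florets)
        seeded = grp[grp["n_seeds"] >= 1]
        sli = sli_from_percentiles(
            seeded["percentile"].to_numpy(),
            seeded["n_seeds"].to_numpy(),
            seed_level=seed_level,
        )
        rows.append(
            dict(inflorescence_id=infl, n_florets=n_florets, n_seeds=n_seeds,
                 s=s, sli=sli, w=seed_weight(s))
        )
    out = pd.DataFrame(
        rows, columns=["inflorescence_id", "n_florets", "n_seeds", "s", "sli", "w"]
    )
    return out.set_index("inflorescence_id")
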