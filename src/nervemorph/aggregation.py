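"""Person-level aggregation: averages, subsamples, diameter compositions.

The analysis layer never works on raw pooled fibres: to keep participants
with wildly different fibre counts comparable, it reduces each participant
either to person-specific averages of the four morphometrics or to a fixed
random subsample of 100 fibres.  For the compositional analysis, fibre
diameters are cut into six half-open bins

    I [0, 2), II [2, 4), III [4, 6), IV [6, 8), V [8, 10), VI [10, inf)

(in um); per-participant bin percentages sum to 100 and are carried into
log-ratios ln(p_k / p_I) against the smallest-diameter bin.  Empty bins are
replaced multiplicatively by half the smallest observable proportion,
0.5 * (100 / n_i), with the remaining bins rescaled so closure is preserved
before taking logs.
"""

from __future__ import annotations

import logging
import zlib

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "BIN_EDGES_UM", "BIN_LABELS",
    "person_averages", "subsample_fibres", "bin_composition",
]

BIN_EDGES_UM = np.array([0.0, 2.0, 4.0, 6.0, 8.0, 10.0, np.inf])
BIN_LABELS = ["bin1", "bin2", "bin3", "bin4", "bin5", "bin6"]

_METRICS = {
    "mean_fibre_diameter_um": "fibre_diameter_um",
    "mean_axon_diameter_um": "axon_diameter_um",
    "mean_myelin_thickness_um": "myelin_thickness_um",
    "mean_g_ratio": "g_ratio",
}


def person_averages(fibres: pd.DataFrame,
                    participants: pd.DataFrame | None = None) -> pd.DataFrame:
    """Person-specific arithmetic means of the morphometrics.

    ``fibres`` must already be validity-filtered.  If a ``participants``
    table is given, its columns (age, sex, covariates, density) are merged
    in; participants with no valid fibres are dropped with a warning.
    """
    if len(fibres) == 0:
        raise ValueError("no fibres to aggregate")
    grouped = fibres.groupby("participant_id", sort=True)
    out = grouped.agg(**{k: (v, "mean") for k, v in _METRICS.items()})
    out["n_fibres"] = grouped.size()
    out = out.reset_index()
    if participants is not None:
        missing = set(participants["participant_id"]) - set(out["participant_id"])
        if missing:
            logger.warning("participants with zero valid fibres dropped: %s",
                           sorted(missing))
        out = out.merge(participants, on="participant_id", how="inner")
        if "density_true" in out.columns and "density_per_mm2" not in out.columns:
            out = out.rename(columns={"density_true": "density_per_mm2"})
    return out


def _participant_rng(seed: int, participant_id) -> np.random.Generator:
    # stable per-participant stream: CRC of the id mixed into the seed
    key = zlib.crc32(str(participant_id).encode())
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


def subsample_fibres(fibres: pd.DataFrame,
                     n_per_participant: int = 100,
                     seed: int = 0) -> pd.DataFrame:
    """Uniform without-replacement subsample per participant.

    Deterministic per (seed, participant_id): re-running with the same
    seed reproduces the identical selection regardless of participant
    order.  Participants with fewer than ``n_per_participant`` fibres
    contribute all their fibres (logged).
    """
    parts = []
    for pid, grp in fibres.groupby("participant_id", sort=True):
        if len(grp) <= n_per_participant:
            if len(grp) < n_per_participant:
                logger.info("participant %s has only %d fibres; keeping all",
                            pid, len(grp))
            parts.append(grp)
            continue
        rng = _participant_rng(seed, pid)
        idx = rng.choice(len(grp), size=n_per_participant, replace=False)
        parts.append(grp.iloc[np.sort(idx)])
    return pd.concat(parts, ignore_index=True)


def bin_composition(fibres: pd.DataFrame) -> pd.DataFrame:
    """Six-bin diameter composition and reference log-ratios per participant.

    Returns one row per participant with columns ``p1..p6`` (percentages,
    closure to 100 maintained through zero replacement) and ``lr2..lr6``
    = ln(p_k / p1).  The number of zero-replaced cells is recorded in
    ``df.attrs['n_zero_replaced']``.
    """
    d = fibres["fibre_diameter_um"].to_numpy(dtype=float)
    codes = np.digitize(d, BIN_EDGES_UM[1:-1], right=False)  # 0..5
    rows = []
    n_replaced = 0
    for pid, grp_idx in fibres.groupby("participant_id", sort=True).indices.items():
        n_i = len(grp_idx)
        counts = np.bincount(codes[grp_idx], minlength=6).astype(float)
        pct = 100.0 * counts / n_i
        zero = pct == 0.0
        if zero.any():
            # cap so replacement mass never exceeds half the composition
            delta = min(0.5 * (100.0 / n_i), 50.0 / zero.sum())
            n_replaced += int(zero.sum())
            pct = np.where(zero, delta,
                           pct * (100.0 - zero.sum() * delta) / 100.0)
        rows.append({"participant_id": pid, "n_fibres": n_i,
                     **{f"p{k + 1}": pct[k] for k in range(6)},
                     **{f"lr{k + 1}": np.log(pct[k] / pct[0])
                        for k in range(1, 6)}})
    out = pd.DataFrame(rows)
    out.attrs["n_zero_replaced"] = n_replaced
    return out
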