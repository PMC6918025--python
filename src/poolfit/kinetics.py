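"""Enzyme kinetics: absorbance-slope rate conversion and Michaelis-Menten fits.

NAD(P)H-linked reductase assays read out as a loss of absorbance at 340 nm;
the slope is converted to a specific activity in nkat/mg (nmol substrate
converted per second per mg protein) via the Beer-Lambert law.  Saturation
curves v(S) are fitted directly to the Michaelis-Menten form
v = Vmax * S / (Km + S) by nonlinear least squares — no Lineweaver-Burk
linearization, which biases parameters under additive noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

#: NADPH molar extinction coefficient at 340 nm, mM^-1 cm^-1 (standard value).
NADPH_EPSILON_340 = 6.22


@dataclass(frozen=True)
class MMFit:
    """A fitted Michaelis-Menten curve.

    Km in mM, Vmax in nkat/mg; standard errors from the asymptotic
    covariance of the least-squares fit.
    """

    km: float
    vmax: float
    km_se: float
    vmax_se: float
    rss: float
    n_points: int

    def __post_init__(self) -> None:
        if self.km <= 0 or self.vmax <= 0:
            raise ValueError("fitted Km and Vmax must be positive")

    def predict(self, s) -> np.ndarray:
        return michaelis_menten(np.asarray(s, dtype=float), self.vmax, self.km)


def michaelis_menten(s, vmax: float, km: float):
    """v = Vmax * S / (Km + S)."""
    s = np.asarray(s, dtype=float)
    return vmax * s / (km + s)


def rate_from_absorbance(
    slope: float,
    epsilon: float = NADPH_EPSILON_340,
    path_cm: float = 1.0,
    volume_l: float = 2e-4,
    protein_mg: float = 1.0,
) -> float:
    """Convert an absorbance slope (AU/min) to specific activity (nkat/mg).

    |slope| / (epsilon * path) gives the concentration change in mM/min;
    times the reaction volume (L) gives mmol/min * 1e-3 = nmol/min * 1e6;
    divided by 60 gives nmol/s (nkat); divided by protein (mg) gives nkat/mg.
    Path length is an explicit input because the optical path of a plate
    well depends on the fill volume.
    """
    if epsilon <= 0 or path_cm <= 0 or volume_l <= 0:
        raise ValueError("epsilon, path and volume must be positive")
    if protein_mg <= 0:
        raise ValueError("protein mass must be positive")
    mm_per_min = abs(slope) / (epsilon * path_cm)
    nmol_per_s = mm_per_min * volume_l * 1e6 / 60.0
    return nmol_per_s / protein_mg


def fit_michaelis_menten(rates: pd.DataFrame) -> MMFit:
    """Fit Vmax and Km to a rate table with columns ``S`` (mM), ``v`` (nkat/mg).

    Initialization is deterministic: Vmax0 = max(v), Km0 = the S whose v is
    closest to Vmax0/2 (floored at a small positive value).  Requires at
    least 3 distinct substrate concentrations.  Raises RuntimeError on
    non-convergence, reporting the initializer and a data summary.
    """
    s = np.asarray(rates["S"], dtype=float)
    v = np.asarray(rates["v"], dtype=float)
    if len(np.unique(s)) < 3:
        raise ValueError("need >= 3 distinct substrate concentrations")
    vmax0 = float(v.max())
    if vmax0 <= 0:
        raise ValueError("all rates are zero; nothing to fit")
    km0 = float(s[np.argmin(np.abs(v - vmax0 / 2.0))])
    km0 = max(km0, 1e-6)
    try:
        popt, pcov = curve_fit(
            michaelis_menten,
            s,
            v,
            p0=(vmax0, km0),
            bounds=((0.0, 0.0), (np.inf, np.inf)),
            maxfev=10000,
        )
    except RuntimeError as exc:
        raise RuntimeError(
            f"Michaelis-Menten fit did not converge "
            f"(init Vmax0={vmax0:g}, Km0={km0:g}; n={len(s)}, "
            f"S range {s.min():g}-{s.max():g} mM)"
        ) from exc
    vmax, km = popt
    se = np.sqrt(np.diag(pcov))
    rss = float(((v - michaelis_menten(s, vmax, km)) ** 2).sum())
    return MMFit(
        km=float(km),
        vmax=float(vmax),
        km_se=float(se[1]),
        vmax_se=float(se[0]),
        rss=rss,
        n_points=len(s),
    )


def read_rate_table(path) -> pd.DataFrame:
    """Read a rate table TSV with columns substrate, S, v[, replicate]."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("S", "v") if c not in df.columns]
    if missing:
        raise ValueError(f"rate table missing columns: {', '.join(missing)}")
    if (df["S"] < 0).any() or (df["v"] < 0).any():
        raise ValueError("S and v must be nonnegative")
    return df


def write_rate_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
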