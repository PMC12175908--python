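"""Per-motif dissociation constants from NMR titration intensity decays.

During a titration of a fixed concentration ``P`` of the observed (labelled)
protein with increasing total ligand ``L``, binding broadens interfacial
peaks, so the fraction bound is read from the intensity decay,
``fb = 1 - I/I0``.  Because ``P`` is comparable to the fitted constants, fb is
modelled with the single-site depletion (quadratic) isotherm

.. math::

    f_b(L) = \\frac{(P + L + K_d) - \\sqrt{(P + L + K_d)^2 - 4 P L}}{2P}

rather than the ``L >> P`` hyperbola.  Kd is fitted per residue by bounded
least squares and summarised per motif as mean ± sample SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "TitrationSeries",
    "BindingFit",
    "fraction_bound",
    "fraction_bound_series",
    "fit_kd",
    "fit_kd_table",
    "motif_kd_summary",
]


def fraction_bound(ligand, receptor_conc: float, kd: float):
    """Quadratic single-site depletion isotherm (vectorized in ligand)."""
    lig = np.asarray(ligand, dtype=float)
    p = receptor_conc
    s = p + lig + kd
    fb = (s - np.sqrt(np.maximum(s**2 - 4.0 * p * lig, 0.0))) / (2.0 * p)
    return fb if fb.ndim else float(fb)


@dataclass
class TitrationSeries:
    """Per-residue I/I0 over a ligand concentration series.

    ``data`` columns: residue, motif, ligand_conc, ratio (I/I0).
    """

    receptor_conc: float
    data: pd.DataFrame
    motif_map: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.receptor_conc <= 0:
            raise ValueError("receptor concentration must be positive")
        required = {"residue", "ligand_conc", "ratio"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"titration table needs columns {sorted(required)}")


@dataclass
class BindingFit:
    """Per-residue Kd estimates and per-motif mean ± SD summary."""

    residue_fits: pd.DataFrame   # residue, motif, kd, rmsd, converged
    motif_summary: pd.DataFrame  # motif, kd_mean, kd_sd, n_residues


def fraction_bound_series(series: TitrationSeries) -> pd.DataFrame:
    """fb(L) = 1 - I/I0 per residue, clipped to [0, 1].

    Noise can push I/I0 slightly above 1; those points clamp to fb = 0.
    """
    df = series.data.copy()
    df["fb"] = np.clip(1.0 - df["ratio"].to_numpy(dtype=float), 0.0, 1.0)
    return df


def fit_kd(ligand: np.ndarray, fb: np.ndarray, receptor_conc: float,
           kd_bounds: tuple[float, float] = (1e-3, 1e6)) -> dict:
    """Least-squares fit of the depletion isotherm to one residue's fb(L).

    Requires at least 3 concentrations with fb > 0.  Returns a dict with
    ``kd``, ``rmsd`` and ``converged``.
    """
    ligand = np.asarray(ligand, dtype=float)
    fb = np.asarray(fb, dtype=float)
    if np.count_nonzero(fb > 0) < 3:
        return {"kd": np.nan, "rmsd": np.nan, "converged": False}
    # half-saturation initial guess
    mid = np.interp(0.5, np.clip(fb, 0, 1), ligand) if fb.max() >= 0.5 else ligand[-1]
    x0 = np.clip(mid, *kd_bounds)

    def resid(log_kd):
        return fraction_bound(ligand, receptor_conc, np.exp(log_kd[0])) - fb

    res = least_squares(
        resid,
        x0=[np.log(x0)],
        bounds=([np.log(kd_bounds[0])], [np.log(kd_bounds[1])]),
    )
    kd = float(np.exp(res.x[0]))
    rmsd = float(np.sqrt(np.mean(res.fun**2)))
    return {"kd": kd, "rmsd": rmsd, "converged": bool(res.success)}


def fit_kd_table(series: TitrationSeries) -> pd.DataFrame:
    """Fit Kd for every residue in a titration series."""
    df = fraction_bound_series(series)
    rows = []
    for res, grp in df.groupby("residue"):
        grp = grp.sort_values("ligand_conc")
        fit = fit_kd(
            grp["ligand_conc"].to_numpy(),
            grp["fb"].to_numpy(),
            series.receptor_conc,
        )
        motif = grp["motif"].iloc[0] if "motif" in grp.columns else ""
        rows.append({"residue": res, "motif": motif, **fit})
    return pd.DataFrame(rows)


def motif_kd_summary(fits: pd.DataFrame,
                     motif_map: dict[str, list[int]] | None = None) -> BindingFit:
    """Per-motif mean ± sample SD over converged residue fits.

    The ± figure uses the n−1 (sample) standard deviation.  Motifs with fewer
    than 2 converged residues are reported with SD NaN; empty motifs error.
    """
    fits = fits.copy()
    if motif_map is not None:
        res_to_motif = {r: m for m, residues in motif_map.items() for r in residues}
        fits["motif"] = fits["residue"].map(res_to_motif)
    rows = []
    for motif, grp in fits.groupby("motif"):
        ok = grp[grp["converged"] & np.isfinite(grp["kd"])]
        if len(ok) == 0:
            raise ValueError(f"motif {motif}: no converged residue fits")
        rows.append(
            {
                "motif": motif,
                "kd_mean": float(ok["kd"].mean()),
                "kd_sd": float(ok["kd"].std(ddof=1)) if len(ok) > 1 else np.nan,
                "n_residues": int(len(ok)),
            }
        )
    return BindingFit(residue_fits=fits, motif_summary=pd.DataFrame(rows))
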