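"""Residue-wise conformational entropy from torsion-angle distributions.

For every torsion angle the range [−π, π) is divided into ``n`` bins (default
35) and the ensemble-weight-reweighted probability :math:`P_i` of each bin is
accumulated.  The per-torsion Shannon entropy with discretization and
undersampling corrections is

.. math::

    S = -\\Big[\\sum_{i=1}^{n} P_i \\ln(P_i h) + \\frac{n-1}{2N}\\Big]

with bin width ``h`` (radians) and frame count ``N``.  Note the undersampling
term is subtracted from the entropy here (the form used by the reference
analysis); the conventional Miller–Madow correction *adds* it, and is
available via ``correction="miller-madow"``.  Per-residue entropy sums the
residue's torsions, and the energy form multiplies by RT at 310 K.

On coarse one-bead-per-residue chains the only available backbone torsion is
the Cα pseudo-dihedral over beads (i−1, i, i+1, i+2); on backbone frames
(N, CA, C atoms) true φ/ψ are computed (ω excluded as essentially rigid).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import ranksums

GAS_CONSTANT = 8.314462618e-3  # kJ mol^-1 K^-1

__all__ = [
    "TorsionSet",
    "EntropyProfile",
    "dihedral",
    "extract_torsions",
    "torsion_entropy",
    "residue_entropy_profile",
    "entropy_contact_comparison",
]


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray,
             p3: np.ndarray) -> np.ndarray:
    """Signed dihedral angle(s) in radians, IUPAC convention, in [−π, π)."""
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1 = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    v = b0 - np.sum(b0 * b1, axis=-1, keepdims=True) * b1
    w = b2 - np.sum(b2 * b1, axis=-1, keepdims=True) * b1
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1, v) * w, axis=-1)
    ang = np.arctan2(y, x)
    return np.where(ang >= np.pi, ang - 2 * np.pi, ang)


@dataclass
class TorsionSet:
    """Torsion angles per residue over frames.

    ``angles`` maps residue number → {torsion name → (n_frames,) array in
    radians}.  Residues whose geometry does not define a torsion (termini)
    simply lack the entry.
    """

    angles: dict[int, dict[str, np.ndarray]]
    n_frames: int
    chain: str = "A"

    def torsion_count(self) -> int:
        return sum(len(v) for v in self.angles.values())


def extract_torsions(ensemble, chain: str = "A") -> TorsionSet:
    """Torsion angles for every residue of a chain.

    Backbone chains (repeating N, CA, C atoms) yield φ and ψ per residue
    where defined; coarse Cα-only chains yield the Cα pseudo-dihedral
    ``eta`` for residues with two neighbours downstream and one upstream.
    """
    names = ensemble.atom_names[chain]
    coords = ensemble.chains[chain]
    res = ensemble.residue_numbers[chain]
    nf = coords.shape[0]
    angles: dict[int, dict[str, np.ndarray]] = {}
    if set(np.unique(names)) >= {"N", "CA", "C"}:
        residues = np.unique(res)
        atom = {}
        for i, (r, a) in enumerate(zip(res, names)):
            atom[(int(r), str(a))] = i

        def pos(r, a):
            idx = atom.get((r, a))
            return None if idx is None else coords[:, idx]

        for r in residues:
            entry = {}
            prev_c, n_, ca, c_ = pos(r - 1, "C"), pos(r, "N"), pos(r, "CA"), pos(r, "C")
            next_n = pos(r + 1, "N")
            if all(p is not None for p in (prev_c, n_, ca, c_)):
                entry["phi"] = dihedral(prev_c, n_, ca, c_)
            if all(p is not None for p in (n_, ca, c_, next_n)):
                entry["psi"] = dihedral(n_, ca, c_, next_n)
            if entry:
                angles[int(r)] = entry
    else:
        ca = ensemble.ca_coords(chain)
        rmap = ensemble.residue_map(chain)
        n = ca.shape[1]
        for i in range(1, n - 2):
            angles[rmap.number(i)] = {
                "eta": dihedral(ca[:, i - 1], ca[:, i], ca[:, i + 1], ca[:, i + 2])
            }
    return TorsionSet(angles=angles, n_frames=nf, chain=chain)


def torsion_entropy(angles: np.ndarray, weights: np.ndarray | None = None,
                    n_bins: int = 35, correction: str = "subtracted",
                    n_frames: int | None = None) -> float:
    """Corrected Shannon entropy (nats) of one torsion's weighted histogram.

    ``correction``: ``"subtracted"`` subtracts (n−1)/(2N) inside the negated
    bracket; ``"miller-madow"`` adds it to the entropy; ``"none"`` omits it.
    ``n_frames`` defaults to the raw frame count (not the effective sample
    size of the weights).
    """
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise ValueError("no angles supplied")
    if weights is None:
        weights = np.full(angles.shape, 1.0 / angles.size)
    weights = np.asarray(weights, dtype=float)
    weights = weights / weights.sum()
    h = 2.0 * np.pi / n_bins
    wrapped = np.mod(angles + np.pi, 2.0 * np.pi) - np.pi
    p, _ = np.histogram(wrapped, bins=n_bins, range=(-np.pi, np.pi),
                        weights=weights)
    mask = p > 0
    raw = -float(np.sum(p[mask] * np.log(p[mask] * h)))
    if n_frames is None:
        n_frames = angles.size
    corr = (n_bins - 1) / (2.0 * n_frames)
    if correction == "subtracted":
        return raw - corr
    if correction == "miller-madow":
        return raw + corr
    if correction == "none":
        return raw
    raise ValueError(f"unknown correction {correction!r}")


@dataclass
class EntropyProfile:
    """Residue-wise entropy (nats) and its RT energy form (kJ/mol)."""

    table: pd.DataFrame  # residue, entropy, entropy_rt, n_torsions
    temperature: float

    def __getitem__(self, residue: int) -> float:
        row = self.table[self.table["residue"] == residue]
        return float(row["entropy"].iloc[0])


def residue_entropy_profile(torsions: TorsionSet,
                            weights: np.ndarray | None = None,
                            n_bins: int = 35,
                            temperature: float = 310.0,
                            correction: str = "subtracted") -> EntropyProfile:
    """Per-residue entropy: sum of the residue's torsion entropies, ×RT.

    ``entropy_rt`` is S·R·T in kJ/mol at ``temperature`` (default 310 K).
    """
    rows = []
    for res, tors in sorted(torsions.angles.items()):
        s = sum(
            torsion_entropy(a, weights, n_bins=n_bins, correction=correction,
                            n_frames=torsions.n_frames)
            for a in tors.values()
        )
        rows.append(
            {
                "residue": res,
                "entropy": s,
                "entropy_rt": s * GAS_CONSTANT * temperature,
                "n_torsions": len(tors),
            }
        )
    return EntropyProfile(table=pd.DataFrame(rows), temperature=temperature)


def entropy_contact_comparison(profile: EntropyProfile,
                               contact_frequency: dict[int, float] | pd.Series,
                               low: float = 0.2, high: float = 0.6,
                               min_group: int = 3) -> dict:
    """Compare entropies of low- vs high-contact residues by rank-sum test.

    Residues with contact frequency below ``low`` form the low group, above
    ``high`` the high group (the band in between is dropped).  Returns group
    statistics, the two-sided Wilcoxon rank-sum p value, and a significance
    band: ``**`` (p < 0.01), ``*`` (0.01–0.05), ``NS`` (> 0.05).  Groups
    smaller than ``min_group`` skip the test with a flag.
    """
    freq = pd.Series(contact_frequency)
    tab = profile.table.set_index("residue")["entropy_rt"]
    common = tab.index.intersection(freq.index)
    freq = freq.loc[common]
    vals = tab.loc[common]
    low_vals = vals[freq < low].to_numpy()
    high_vals = vals[freq > high].to_numpy()
    out = {
        "n_low": int(len(low_vals)),
        "n_high": int(len(high_vals)),
        "low_mean": float(np.mean(low_vals)) if len(low_vals) else np.nan,
        "high_mean": float(np.mean(high_vals)) if len(high_vals) else np.nan,
    }
    if len(low_vals) < min_group or len(high_vals) < min_group:
        out.update({"p_value": np.nan, "significance": "skipped", "tested": False})
        return out
    stat, p = ranksums(low_vals, high_vals)
    band = "**" if p < 0.01 else ("*" if p <= 0.05 else "NS")
    out.update(
        {"statistic": float(stat), "p_value": float(p), "significance": band,
         "tested": True}
    )
    return out
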