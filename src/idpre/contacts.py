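"""Weighted intra-chain and inter-chain contact statistics.

Contacts are defined on the same 4-residue segment scheme as the landscape
features: a segment pair is in contact in a frame when the minimum bead–bead
distance between the two windows is at or below a cutoff (default 8 Å for
Cα-only coarse models; 4.5 Å would suit heavy-atom frames).  Contact
frequencies are weighted fractions of frames in contact; per-state maps
restrict and renormalize the weights within each state.  For intra-chain maps
short-range pairs (two segments apart or closer) are omitted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .landscape import segment_windows, _segment_min_distance_matrix

__all__ = [
    "ContactMap",
    "InteractionProfile",
    "frame_contacts",
    "contact_frequency_map",
    "interaction_profile",
    "state_specific_contacts",
]

CA_CUTOFF = 8.0
HEAVY_ATOM_CUTOFF = 4.5


@dataclass
class ContactMap:
    """Weighted segment-pair contact frequencies in [0, 1]."""

    windows_a: list[tuple[int, int]]
    windows_b: list[tuple[int, int]]
    frequencies: np.ndarray         # (n_seg_a, n_seg_b)
    cutoff: float
    scope: str                      # "intra" | "inter"


@dataclass
class InteractionProfile:
    """Per-segment probability of contacting the partner chain."""

    windows: list[tuple[int, int]]
    segment_probability: np.ndarray
    residue_probability: np.ndarray
    cutoff: float


def _min_dist_blocks(coords_a: np.ndarray, coords_b: np.ndarray,
                     windows_a, windows_b) -> np.ndarray:
    """(F, n_seg_a, n_seg_b) min distances between windows of two chains."""
    f = coords_a.shape[0]
    wa = windows_a[0][1] - windows_a[0][0]
    wb = windows_b[0][1] - windows_b[0][0]

    def pad(c, n_seg, w):
        need = n_seg * w - c.shape[1]
        if need:
            big = np.full((f, c.shape[1] + need, 3), 1e6)
            big[:, : c.shape[1]] = c
            return big
        return c

    a = pad(coords_a, len(windows_a), wa)
    b = pad(coords_b, len(windows_b), wb)
    d = np.linalg.norm(a[:, :, None, :] - b[:, None, :, :], axis=-1)
    d = d.reshape(f, len(windows_a), wa, len(windows_b), wb)
    return d.min(axis=(2, 4))


def frame_contacts(coords_a: np.ndarray, coords_b: np.ndarray | None,
                   cutoff: float = CA_CUTOFF, window: int = 4,
                   exclude_within: int = 2) -> np.ndarray:
    """Boolean segment-pair contact matrix for a single frame.

    ``coords_a`` is (n, 3); ``coords_b`` None means intra-chain, in which case
    pairs separated by ``exclude_within`` segments or fewer are masked False.
    """
    a = np.asarray(coords_a, dtype=float)[None]
    intra = coords_b is None
    b = a if intra else np.asarray(coords_b, dtype=float)[None]
    wa = segment_windows(a.shape[1], window)
    wb = wa if intra else segment_windows(b.shape[1], window)
    d = _min_dist_blocks(a, b, wa, wb)[0]
    contact = d <= cutoff
    if intra:
        idx = np.arange(len(wa))
        near = np.abs(idx[:, None] - idx[None, :]) <= exclude_within
        contact[near] = False
    return contact


def contact_frequency_map(ensemble, weights: np.ndarray | None = None,
                          chain_a: str = "A", chain_b: str | None = None,
                          cutoff: float = CA_CUTOFF, window: int = 4,
                          exclude_within: int = 2, per_state: bool = False,
                          chunk: int = 200):
    """Weighted segment-pair contact frequency map (intra- or inter-chain).

    Returns a :class:`ContactMap`, or a dict state → map when ``per_state``
    (weights restricted to the state and renormalized; a state with zero
    total weight is an error).
    """
    if weights is None:
        weights = ensemble.prior_weights
    weights = np.asarray(weights, dtype=float)
    if not np.isclose(weights.sum(), 1.0):
        raise ValueError("weights must be normalized")
    ca = ensemble.ca_coords(chain_a)
    intra = chain_b is None or chain_b == chain_a
    cb = ca if intra else ensemble.ca_coords(chain_b)
    wa = segment_windows(ca.shape[1], window)
    wb = wa if intra else segment_windows(cb.shape[1], window)
    nf = ca.shape[0]
    indicators = np.empty((nf, len(wa), len(wb)), dtype=bool)
    for lo in range(0, nf, chunk):
        hi = min(lo + chunk, nf)
        d = _min_dist_blocks(ca[lo:hi], cb[lo:hi], wa, wb)
        indicators[lo:hi] = d <= cutoff
    if intra:
        idx = np.arange(len(wa))
        near = np.abs(idx[:, None] - idx[None, :]) <= exclude_within
        indicators[:, near] = False
    scope = "intra" if intra else "inter"

    def build(w):
        w = w / w.sum()
        freq = np.tensordot(w, indicators, axes=(0, 0))
        return ContactMap(wa, wb, freq, cutoff, scope)

    if not per_state:
        return build(weights)
    out = {}
    for s in np.unique(ensemble.states):
        mask = ensemble.states == s
        if weights[mask].sum() <= 0:
            raise ValueError(f"state {s} has zero total weight")
        w = np.where(mask, weights, 0.0)
        out[str(s)] = build(w)
    return out


def interaction_profile(ensemble, weights: np.ndarray | None = None,
                        chain_a: str = "A", chain_b: str = "B",
                        cutoff: float = CA_CUTOFF, window: int = 4,
                        chunk: int = 200) -> dict[str, InteractionProfile]:
    """Fraction of (weighted) time each segment contacts the partner chain.

    Computed for both chains; the per-residue expansion assigns each residue
    its segment's probability.
    """
    if weights is None:
        weights = ensemble.prior_weights
    weights = np.asarray(weights, dtype=float)
    weights = weights / weights.sum()
    ca = ensemble.ca_coords(chain_a)
    cb = ensemble.ca_coords(chain_b)
    wa = segment_windows(ca.shape[1], window)
    wb = segment_windows(cb.shape[1], window)
    nf = ca.shape[0]
    any_a = np.empty((nf, len(wa)))
    any_b = np.empty((nf, len(wb)))
    for lo in range(0, nf, chunk):
        hi = min(lo + chunk, nf)
        d = _min_dist_blocks(ca[lo:hi], cb[lo:hi], wa, wb)
        contact = d <= cutoff
        any_a[lo:hi] = contact.any(axis=2)
        any_b[lo:hi] = contact.any(axis=1)

    def expand(windows, seg_prob, n_res):
        out = np.empty(n_res)
        for (s, e), p in zip(windows, seg_prob):
            out[s:e] = p
        return out

    prof_a = weights @ any_a
    prof_b = weights @ any_b
    return {
        chain_a: InteractionProfile(wa, prof_a, expand(wa, prof_a, ca.shape[1]),
                                    cutoff),
        chain_b: InteractionProfile(wb, prof_b, expand(wb, prof_b, cb.shape[1]),
                                    cutoff),
    }


def state_specific_contacts(per_state_maps: dict[str, ContactMap],
                            high_thresh: float = 0.6,
                            low_thresh: float = 0.2,
                            top: int | None = 3) -> pd.DataFrame:
    """Contacts highly represented in one state, minimally in the others.

    A segment pair is specific to state ``s`` when its frequency there is at
    least ``high_thresh`` while its maximum over the other states is at most
    ``low_thresh``.  Returns the (optionally top-``top`` per state) ranked
    long-format table.
    """
    if len(per_state_maps) < 2:
        raise ValueError("state-specific contacts need at least 2 states")
    states = list(per_state_maps)
    stack = np.stack([per_state_maps[s].frequencies for s in states])
    rows = []
    for k, s in enumerate(states):
        others = np.delete(stack, k, axis=0).max(axis=0)
        freq = stack[k]
        upper = np.triu(np.ones_like(freq, dtype=bool))
        if per_state_maps[s].scope != "intra":
            upper[:] = True
        mask = (freq >= high_thresh) & (others <= low_thresh) & upper
        for a, b in zip(*np.nonzero(mask)):
            rows.append(
                {
                    "state": s,
                    "segment_a": int(a),
                    "segment_b": int(b),
                    "frequency": float(freq[a, b]),
                    "max_other": float(others[a, b]),
                }
            )
    df = pd.DataFrame(
        rows, columns=["state", "segment_a", "segment_b", "frequency", "max_other"]
    )
    if len(df):
        df = (
            df.sort_values(["state", "frequency"], ascending=[True, False])
            .groupby("state", group_keys=False)
            .head(top if top is not None else len(df))
            .reset_index(drop=True)
        )
    return df
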