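"""Synthetic multi-state ensembles and synthetic PRE / titration observables.

The generator emulates the study system at desk scale: a ~311-residue
disordered chain carrying short helical LD motifs, bound to a rigid four-helix
receptor proxy through two motifs at a time (one per receptor face), in four
interconverting states with known ground-truth state populations.  Observables
(PRE intensity ratios, titration intensity decays) are produced by the
package's own forward models plus configurable multiplicative noise, so every
downstream stage can be validated against known truth.

Chains are coarse-grained to one bead per residue with fixed bond length.
Unanchored chain regions are sampled as persistent (von-Mises–Fisher
correlated) self-avoiding walks; helical segments are emitted as rigid helix
templates; linkers between anchored motifs are Brownian bridges projected to
constant bond length by iterative forward/backward passes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .ensemble import Ensemble
from .pre import (
    PhysicalConstants,
    SpinLabelSite,
    gamma2_ensemble,
    gamma2_to_intensity,
    site_gamma2_matrix,
)

__all__ = [
    "ChainSpec",
    "ComplexStateSpec",
    "GroundTruth",
    "ReceptorProxy",
    "GenerationError",
    "build_receptor",
    "default_states",
    "default_sites",
    "sample_apo_ensemble",
    "sample_complex_ensemble",
    "synthesize_pre",
    "synthesize_titration",
    "SyntheticPRE",
]


class GenerationError(RuntimeError):
    """Raised when conformer generation fails under the given settings."""


# ---------------------------------------------------------------------------
# specifications


@dataclass
class ChainSpec:
    """Coarse one-bead-per-residue disordered chain with helical motifs.

    ``helical_segments`` maps motif name to a 1-based inclusive residue range.
    The default layout approximates the LD1/LD2/LD4 positions of a 311-residue
    N-terminal disordered domain (boundaries estimated from spin-label and
    mutation sites; configurable).  ``persistence_length`` (Å) sets the
    stiffness of non-helical regions and thereby the coil dimensions.
    """

    length: int = 311
    helical_segments: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {"LD1": (3, 14), "LD2": (144, 155), "LD4": (263, 274)}
    )
    bond_length: float = 3.8
    excluded_volume_radius: float = 2.0
    persistence_length: float = 6.5

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("chain length must be >= 1")
        if self.bond_length <= 0:
            raise ValueError("bond_length must be positive")
        if self.excluded_volume_radius < 0:
            raise ValueError("excluded_volume_radius must be nonnegative")
        ranges = sorted(self.helical_segments.values())
        for (s, e) in ranges:
            if not (1 <= s <= e <= self.length):
                raise ValueError(f"segment ({s},{e}) outside [1,{self.length}]")
        for (_, e1), (s2, _) in zip(ranges, ranges[1:]):
            if s2 <= e1:
                raise ValueError("helical segments overlap")


@dataclass
class ComplexStateSpec:
    """One bound state: exactly two motifs anchored on distinct receptor faces."""

    state_id: str
    anchored_motifs: dict[str, str]  # motif name -> face ("a1a4" | "a2a3")

    def __post_init__(self) -> None:
        if len(self.anchored_motifs) != 2:
            raise ValueError(f"state {self.state_id}: exactly two motifs required")
        faces = list(self.anchored_motifs.values())
        if len(set(faces)) != 2:
            raise ValueError(f"state {self.state_id}: motifs must be on distinct faces")


@dataclass
class GroundTruth:
    """Known generating parameters for synthetic observables."""

    state_weights: dict[str, float] = field(
        default_factory=lambda: {"I": 0.25, "II": 0.25, "III": 0.25, "IV": 0.25}
    )
    kd_true: dict[str, float] = field(
        default_factory=lambda: {"LD1": 17.0, "LD2": 7.0, "LD4": 13.0}
    )
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        w = np.array(list(self.state_weights.values()), dtype=float)
        if np.any(w < 0):
            raise ValueError("state weights must be nonnegative")
        if not np.isclose(w.sum(), 1.0):
            raise ValueError("state weights must sum to 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass
class ReceptorProxy:
    """Rigid four-rod helix-bundle stand-in for the folded receptor domain."""

    coords: np.ndarray  # (n_beads, 3)
    residue_numbers: np.ndarray
    anchor_sites: dict[str, np.ndarray]  # face -> (3,) anchor point
    core_radius: float
    half_height: float


def build_receptor(
    n_per_helix: int = 40,
    first_residue: int = 892,
    bundle_half_spacing: float = 5.5,
    rise: float = 1.5,
    anchor_offset: float = 7.0,
) -> ReceptorProxy:
    """Four straight helical rods in a square bundle, two labelled faces.

    Rods are numbered sequentially in native author numbering (default
    892–1051 for 4x40 beads), so label sites such as 984/1006 (third rod) and
    1018/1040 (fourth rod) resolve naturally.  Faces ``a1a4`` (rods 1 and 4)
    and ``a2a3`` (rods 2 and 3) get anchor points just outside the bundle at
    mid-height.
    """
    d = bundle_half_spacing
    xy = np.array([(-d, d), (d, d), (d, -d), (-d, -d)], dtype=float)
    z = (np.arange(n_per_helix) - (n_per_helix - 1) / 2.0) * rise
    coords = np.concatenate(
        [np.column_stack([np.full(n_per_helix, x), np.full(n_per_helix, y), z])
         for x, y in xy]
    )
    residues = np.arange(first_residue, first_residue + 4 * n_per_helix)
    anchors = {
        "a1a4": np.array([-(d + anchor_offset), 0.0, 0.0]),
        "a2a3": np.array([d + anchor_offset, 0.0, 0.0]),
    }
    return ReceptorProxy(
        coords=coords,
        residue_numbers=residues,
        anchor_sites=anchors,
        core_radius=float(np.hypot(d, d) + 3.0),
        half_height=float(z.max()),
    )


def default_states() -> list[ComplexStateSpec]:
    """The four-state layout: LD2 always bound, partnered by LD1 or LD4."""
    return [
        ComplexStateSpec("I", {"LD2": "a2a3", "LD1": "a1a4"}),
        ComplexStateSpec("II", {"LD2": "a2a3", "LD4": "a1a4"}),
        ComplexStateSpec("III", {"LD2": "a1a4", "LD1": "a2a3"}),
        ComplexStateSpec("IV", {"LD2": "a1a4", "LD4": "a2a3"}),
    ]


def default_sites() -> list[SpinLabelSite]:
    """Four receptor spin-label sites mirroring the E984C/Q1006C/K1018C/Q1040C design."""
    return [
        SpinLabelSite("B", 984),
        SpinLabelSite("B", 1006),
        SpinLabelSite("B", 1018),
        SpinLabelSite("B", 1040),
    ]


# ---------------------------------------------------------------------------
# geometry helpers


def _normalize(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    n = np.where(n == 0, 1.0, n)
    return v / n


def _random_unit(rng: np.random.Generator, n: int) -> np.ndarray:
    return _normalize(rng.normal(size=(n, 3)))


def _kappa_from_persistence(lp: float, b: float) -> float:
    """Concentration of the bond-angle distribution giving <cos theta> = exp(-b/lp)."""
    target = np.exp(-b / lp)
    if target < 1e-6:
        return 1e-6

    def langevin(k):
        return 1.0 / np.tanh(k) - 1.0 / k - target

    return brentq(langevin, 1e-6, 1e4)


def _vmf_directions(rng: np.random.Generator, mean: np.ndarray,
                    kappa: float) -> np.ndarray:
    """von-Mises–Fisher samples on the sphere around per-row mean directions."""
    f = mean.shape[0]
    if kappa < 1e-5:
        return _random_unit(rng, f)
    xi = rng.uniform(size=f)
    w = 1.0 + np.log(xi + (1.0 - xi) * np.exp(-2.0 * kappa)) / kappa
    phi = rng.uniform(0.0, 2.0 * np.pi, size=f)
    ref = np.where(
        np.abs(mean[:, 2:3]) < 0.9,
        np.array([0.0, 0.0, 1.0]),
        np.array([1.0, 0.0, 0.0]),
    )
    e1 = _normalize(np.cross(mean, ref))
    e2 = np.cross(mean, e1)
    s = np.sqrt(np.maximum(0.0, 1.0 - w**2))
    return (
        w[:, None] * mean
        + s[:, None] * (np.cos(phi)[:, None] * e1 + np.sin(phi)[:, None] * e2)
    )


def _helix_template(m: int, bond_length: float) -> np.ndarray:
    """Ideal Cα-trace alpha helix (rise 1.5 Å, 100°/residue), first bead at origin,
    axis along +z, scaled so consecutive beads sit exactly one bond apart."""
    k = np.arange(m)
    theta = np.deg2rad(100.0) * k
    raw = np.column_stack([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * k])
    if m > 1:
        raw *= bond_length / np.linalg.norm(raw[1] - raw[0])
    return raw - raw[0]


def _rotation_to(axis: np.ndarray, psi: np.ndarray) -> np.ndarray:
    """(F,3,3) rotations mapping +z to per-row ``axis`` after azimuth ``psi``."""
    f = axis.shape[0]
    cz, sz = np.cos(psi), np.sin(psi)
    rz = np.zeros((f, 3, 3))
    rz[:, 0, 0], rz[:, 0, 1] = cz, -sz
    rz[:, 1, 0], rz[:, 1, 1] = sz, cz
    rz[:, 2, 2] = 1.0
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(np.broadcast_to(z, axis.shape), axis)
    c = np.clip(axis[:, 2], -1.0, 1.0)
    k = np.zeros((f, 3, 3))
    k[:, 0, 1], k[:, 0, 2] = -v[:, 2], v[:, 1]
    k[:, 1, 0], k[:, 1, 2] = v[:, 2], -v[:, 0]
    k[:, 2, 0], k[:, 2, 1] = -v[:, 1], v[:, 0]
    s2 = (v**2).sum(axis=1)
    fac = np.where(s2 > 1e-12, (1.0 - c) / np.where(s2 > 1e-12, s2, 1.0), 0.0)
    align = np.eye(3)[None] + k + fac[:, None, None] * (k @ k)
    flip = c < -1.0 + 1e-9
    if np.any(flip):
        align[flip] = np.diag([1.0, -1.0, -1.0])[None]
    return align @ rz


# ---------------------------------------------------------------------------
# apo sampling


def _grow_apo(spec: ChainSpec, n_frames: int,
              rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Grow self-avoiding persistent chains, vectorized across frames.

    Returns positions (F, n, 3) and a boolean mask of frames whose growth got
    sterically stuck (to be regenerated by the caller).
    """
    n, b = spec.length, spec.bond_length
    pos = np.zeros((n_frames, n, 3))
    dead = np.zeros(n_frames, dtype=bool)
    if n == 1:
        return pos, dead
    kappa = _kappa_from_persistence(spec.persistence_length, b)
    thresh = 2.0 * spec.excluded_volume_radius
    helix_at = {s - 1: (name, s - 1, e - 1) for name, (s, e) in
                spec.helical_segments.items() if s >= 2 and e <= n}
    t = _random_unit(rng, n_frames)
    i = 1
    max_tries = 30
    while i < n:
        if i in helix_at:
            _, s_idx, e_idx = helix_at[i]
            m = e_idx - s_idx + 1
            tmpl = _helix_template(m, b)
            ok = np.zeros(n_frames, dtype=bool)
            beads = np.zeros((n_frames, m, 3))
            active = ~dead
            for _try in range(max_tries):
                idx = np.flatnonzero(active & ~ok)
                if idx.size == 0:
                    break
                psi = rng.uniform(0.0, 2.0 * np.pi, size=idx.size)
                rot = _rotation_to(t[idx], psi)
                start = pos[idx, i - 1] + b * t[idx]
                cand = start[:, None, :] + np.einsum("fab,mb->fma", rot, tmpl)
                if thresh > 0 and i >= 2:
                    d = np.linalg.norm(
                        cand[:, :, None, :] - pos[idx, None, : i - 1, :], axis=-1
                    )
                    good = d.min(axis=(1, 2)) >= thresh
                else:
                    good = np.ones(idx.size, dtype=bool)
                beads[idx[good]] = cand[good]
                ok[idx[good]] = True
            stuck = np.flatnonzero(active & ~ok)
            if stuck.size:
                dead[stuck] = True
                psi = rng.uniform(0.0, 2.0 * np.pi, size=stuck.size)
                rot = _rotation_to(t[stuck], psi)
                start = pos[stuck, i - 1] + b * t[stuck]
                beads[stuck] = start[:, None, :] + np.einsum(
                    "fab,mb->fma", rot, tmpl
                )
            pos[:, i : i + m] = beads
            # exit direction: helix axis (the mean advance direction)
            if m > 1:
                t = _normalize(pos[:, i + m - 1] - pos[:, i])
            i += m
            continue
        accepted = np.zeros(n_frames, dtype=bool)
        new_t = t.copy()
        active = ~dead
        for _try in range(max_tries):
            idx = np.flatnonzero(active & ~accepted)
            if idx.size == 0:
                break
            kk = kappa if _try < max_tries // 2 else 0.0
            d = _vmf_directions(rng, t[idx], kk)
            cand = pos[idx, i - 1] + b * d
            if thresh > 0 and i >= 2:
                dist = np.linalg.norm(
                    cand[:, None, :] - pos[idx, : i - 1, :], axis=-1
                )
                good = dist.min(axis=1) >= thresh
            else:
                good = np.ones(idx.size, dtype=bool)
            gi = idx[good]
            pos[gi, i] = cand[good]
            new_t[gi] = d[good]
            accepted[gi] = True
        stuck = np.flatnonzero(active & ~accepted)
        if stuck.size:
            dead[stuck] = True
            pos[stuck, i] = pos[stuck, i - 1] + b * t[stuck]
        t = new_t
        i += 1
    return pos, dead


def sample_apo_ensemble(spec: ChainSpec, n_frames: int, seed: int = 0,
                        max_rounds: int = 20) -> Ensemble:
    """Sample an ensemble of the unbound disordered chain.

    Self-avoiding persistent coarse chains with rigid helix geometry at the
    configured motif segments; deterministic under ``seed``.  Frames whose
    growth dead-ends sterically are resampled; persistently infeasible
    excluded-volume settings raise :class:`GenerationError`.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    pos, dead = _grow_apo(spec, n_frames, rng)
    rounds = 0
    while dead.any():
        rounds += 1
        if rounds > max_rounds:
            raise GenerationError(
                f"excluded-volume generation failed for {int(dead.sum())} of "
                f"{n_frames} frames after {max_rounds} rounds; decrease "
                f"excluded_volume_radius ({spec.excluded_volume_radius} Å) or "
                "increase persistence_length"
            )
        idx = np.flatnonzero(dead)
        new_pos, new_dead = _grow_apo(spec, idx.size, rng)
        pos[idx] = new_pos
        dead[idx] = new_dead
    return Ensemble(
        chains={"A": pos},
        residue_numbers={"A": np.arange(1, spec.length + 1)},
        states=np.array(["apo"] * n_frames),
    )


# ---------------------------------------------------------------------------
# complex sampling


def _fabrik(p: np.ndarray, a: np.ndarray, bpt: np.ndarray, b: float,
            iters: int = 60, tol: float = 0.05) -> np.ndarray:
    """Project a bridge onto constant bond length with pinned endpoints.

    ``p`` is (F, m+1, 3) including both endpoints; forward/backward passes are
    vectorized across frames.
    """
    m = p.shape[1] - 1

    def safe_dir(v):
        d = _normalize(v)
        bad = np.linalg.norm(d, axis=-1) < 1e-9
        if bad.any():
            d[bad] = np.array([0.0, 0.0, 1.0])
        return d

    for _ in range(iters):
        p[:, -1] = bpt
        for k in range(m - 1, -1, -1):
            d = safe_dir(p[:, k] - p[:, k + 1])
            p[:, k] = p[:, k + 1] + b * d
        p[:, 0] = a
        for k in range(1, m + 1):
            d = safe_dir(p[:, k] - p[:, k - 1])
            p[:, k] = p[:, k - 1] + b * d
        err = np.linalg.norm(p[:, -1] - bpt, axis=1)
        if err.max() < tol:
            break
    return p


def _bridge(a: np.ndarray, bpt: np.ndarray, m_bonds: int, b: float,
            kappa: float, rng: np.random.Generator) -> np.ndarray:
    """Persistent-walk bridge between fixed endpoints, bond-projected.

    A free von-Mises–Fisher walk from ``a`` is sheared linearly so its end
    lands on ``bpt`` (preserving local stiffness, hence coil-like loop
    dimensions), then polished to constant bond length.
    """
    f = a.shape[0]
    p = np.empty((f, m_bonds + 1, 3))
    p[:, 0] = a
    t = _random_unit(rng, f)
    for k in range(1, m_bonds + 1):
        t = _vmf_directions(rng, t, kappa)
        p[:, k] = p[:, k - 1] + b * t
    shift = (bpt - p[:, -1])[:, None, :] * (
        np.arange(m_bonds + 1)[None, :, None] / m_bonds
    )
    p = p + shift
    return _fabrik(p, a, bpt, b, iters=30)


def _reproject_chain(p: np.ndarray, start: np.ndarray, b: float) -> np.ndarray:
    """Restore bond lengths of a free-ended segment by walking from its fixed end.

    ``p`` is (F, m, 3) beads after the fixed start; directions are preserved,
    lengths reset to ``b``.
    """
    prev = start
    for k in range(p.shape[1]):
        d = _normalize(p[:, k] - prev)
        zero = np.linalg.norm(d, axis=1) < 1e-9
        if zero.any():
            d[zero] = _random_unit(np.random.default_rng(0), int(zero.sum()))
        p[:, k] = prev + b * d
        prev = p[:, k]
    return p


def _grow_tail(start: np.ndarray, t0: np.ndarray, m_bonds: int, b: float,
               kappa: float, confine_radius: float,
               rng: np.random.Generator, ev_thresh: float) -> np.ndarray:
    """Free persistent walk from a fixed start, confined to a sphere at origin."""
    f = start.shape[0]
    out = np.zeros((f, m_bonds, 3))
    p = start.copy()
    t = t0.copy()
    window: list[np.ndarray] = []
    for k in range(m_bonds):
        d = _vmf_directions(rng, t, kappa)
        cand = p + b * d
        r = np.linalg.norm(cand, axis=1)
        outside = r > confine_radius
        if outside.any():
            rhat = _normalize(cand[outside])
            d2 = d[outside] - 2.0 * np.sum(d[outside] * rhat, axis=1, keepdims=True) * rhat
            d[outside] = _normalize(d2)
            cand[outside] = p[outside] + b * d[outside]
        if ev_thresh > 0 and len(window) >= 2:
            recent = np.stack(window[-8:], axis=1)  # (F, w, 3)
            for _try in range(8):
                dist = np.linalg.norm(cand[:, None, :] - recent[:, :-1], axis=-1)
                bad = dist.min(axis=1) < ev_thresh
                if not bad.any():
                    break
                d_new = _vmf_directions(rng, t[bad], 0.0)
                cand[bad] = p[bad] + b * d_new
                d[bad] = d_new
        out[:, k] = cand
        window.append(cand)
        p, t = cand, d
    return out


def sample_complex_ensemble(
    chain: ChainSpec,
    states: list[ComplexStateSpec],
    truth: GroundTruth,
    n_frames_per_state: int,
    receptor: ReceptorProxy | None = None,
    anchor_tolerance: float = 2.5,
    loop_persistence: float = 12.0,
    tail_persistence: float = 12.0,
    confine_radius: float = 70.0,
) -> Ensemble:
    """Sample the bound two-chain complex in the given states.

    Each frame anchors the state's two motifs (rigid helices) at the receptor
    faces, bridges the intervening chain with bond-projected Brownian bridges,
    and grows confined persistent tails.  Frames are tagged with their state
    id; ground-truth frame weights (state weight spread uniformly over the
    state's frames) are stored on the returned ensemble.  ``loop_persistence``
    and ``confine_radius`` (Å) set the breadth of the bound-state cloud and
    hence the complex radius of gyration (defaults target ~35 Å for the
    default system, the dimension a compact fuzzy complex of this size shows
    by small-angle scattering).
    """
    if not states:
        raise ValueError("at least one state required")
    if n_frames_per_state < 1:
        raise ValueError("n_frames_per_state must be >= 1")
    if receptor is None:
        receptor = build_receptor()
    rng = np.random.default_rng(truth.seed)
    n, b = chain.length, chain.bond_length
    kappa_tail = _kappa_from_persistence(tail_persistence, b)
    kappa_loop = _kappa_from_persistence(loop_persistence, b)
    ev = 2.0 * chain.excluded_volume_radius

    all_pos, all_states, all_true_w = [], [], []
    for state in states:
        f = n_frames_per_state
        pos = np.zeros((f, n, 3))
        fixed = np.zeros(n, dtype=bool)
        for motif, face in state.anchored_motifs.items():
            if motif not in chain.helical_segments:
                raise GenerationError(
                    f"state {state.state_id}: motif {motif} not defined on chain"
                )
            if face not in receptor.anchor_sites:
                raise GenerationError(
                    f"state {state.state_id}: unknown receptor face {face}"
                )
        motifs = sorted(
            state.anchored_motifs.items(), key=lambda kv: chain.helical_segments[kv[0]]
        )
        for motif, face in motifs:
            s, e = chain.helical_segments[motif]
            s_idx, e_idx = s - 1, e - 1
            m = e_idx - s_idx + 1
            tmpl = _helix_template(m, b)
            tmpl = tmpl - tmpl.mean(axis=0)
            axis = _vmf_directions(rng, np.tile([0.0, 0.0, 1.0], (f, 1)), 20.0)
            psi = rng.uniform(0.0, 2.0 * np.pi, size=f)
            rot = _rotation_to(axis, psi)
            jitter = 0.6 * rng.normal(size=(f, 3))
            jnorm = np.linalg.norm(jitter, axis=1, keepdims=True)
            cap = 0.6 * anchor_tolerance
            jitter *= np.minimum(1.0, cap / np.maximum(jnorm, 1e-9))
            center = receptor.anchor_sites[face][None, :] + jitter
            pos[:, s_idx : e_idx + 1] = center[:, None, :] + np.einsum(
                "fab,mb->fma", rot, tmpl
            )
            fixed[s_idx : e_idx + 1] = True
            mid = pos[:, s_idx : e_idx + 1].mean(axis=1)
            off = np.linalg.norm(mid - receptor.anchor_sites[face], axis=1)
            if off.max() > anchor_tolerance:
                raise GenerationError(
                    f"state {state.state_id}: motif {motif} missed its anchor "
                    f"({off.max():.2f} Å > {anchor_tolerance} Å)"
                )
        # chain regions between / outside fixed blocks
        blocks = []
        start = None
        for i in range(n):
            if fixed[i] and start is None:
                start = i
            elif not fixed[i] and start is not None:
                blocks.append((start, i - 1))
                start = None
        if start is not None:
            blocks.append((start, n - 1))
        # bridges between consecutive fixed blocks
        for (a0, a1), (b0, _) in zip(blocks, blocks[1:]):
            m_bonds = b0 - a1
            gap = np.linalg.norm(pos[:, b0] - pos[:, a1], axis=1)
            if gap.max() > 0.95 * m_bonds * b:
                raise GenerationError(
                    f"state {state.state_id}: anchoring unsatisfiable, linker of "
                    f"{m_bonds} bonds cannot span {gap.max():.1f} Å"
                )
            if m_bonds > 1:
                br = _bridge(pos[:, a1], pos[:, b0], m_bonds, b, kappa_loop, rng)
                pos[:, a1 + 1 : b0] = br[:, 1:-1]
        # head tail (before first block), grown backward
        h0 = blocks[0][0]
        if h0 > 0:
            t0 = _normalize(pos[:, h0] - pos[:, h0 + 1])
            tail = _grow_tail(pos[:, h0], t0, h0, b, kappa_tail,
                              confine_radius, rng, ev)
            pos[:, :h0] = tail[:, ::-1]
        # end tail (after last block)
        e1 = blocks[-1][1]
        if e1 < n - 1:
            t0 = _normalize(pos[:, e1] - pos[:, e1 - 1]) if e1 > 0 else (
                _random_unit(rng, f)
            )
            pos[:, e1 + 1 :] = _grow_tail(
                pos[:, e1], t0, n - 1 - e1, b, kappa_tail, confine_radius, rng, ev
            )
        # steric repair: push non-anchored beads out of the receptor core,
        # then restore bond lengths in every flexible region
        for _ in range(3):
            free = ~fixed
            xy = pos[:, :, :2]
            r_xy = np.linalg.norm(xy, axis=2)
            inside = (
                (r_xy < receptor.core_radius)
                & (np.abs(pos[:, :, 2]) < receptor.half_height + 2.0)
                & free[None, :]
            )
            if not inside.any():
                break
            scale = np.where(
                inside, receptor.core_radius / np.maximum(r_xy, 1e-6), 1.0
            )
            pos[:, :, :2] = xy * scale[:, :, None]
            for (a0, a1), (b0, _) in zip(blocks, blocks[1:]):
                if b0 - a1 > 1:
                    seg = pos[:, a1 : b0 + 1].copy()
                    pos[:, a1 + 1 : b0] = _fabrik(
                        seg, pos[:, a1], pos[:, b0], b, iters=15
                    )[:, 1:-1]
            h0b = blocks[0][0]
            if h0b > 0:
                head = pos[:, :h0b][:, ::-1].copy()
                pos[:, :h0b] = _reproject_chain(head, pos[:, h0b], b)[:, ::-1]
            e1b = blocks[-1][1]
            if e1b < n - 1:
                tail = pos[:, e1b + 1 :].copy()
                pos[:, e1b + 1 :] = _reproject_chain(tail, pos[:, e1b], b)
        all_pos.append(pos)
        all_states.extend([state.state_id] * f)
        sw = truth.state_weights.get(state.state_id)
        if sw is None:
            sw = 1.0 / len(states)
        all_true_w.extend([sw / f] * f)

    chain_coords = np.concatenate(all_pos, axis=0)
    nf = chain_coords.shape[0]
    receptor_coords = np.broadcast_to(
        receptor.coords[None, :, :], (nf,) + receptor.coords.shape
    ).copy()
    true_w = np.array(all_true_w)
    true_w = true_w / true_w.sum()
    return Ensemble(
        chains={"A": chain_coords, "B": receptor_coords},
        residue_numbers={
            "A": np.arange(1, n + 1),
            "B": receptor.residue_numbers,
        },
        states=np.array(all_states, dtype=object),
        true_weights=true_w,
    )


# ---------------------------------------------------------------------------
# synthetic observables


@dataclass
class SyntheticPRE:
    """Synthetic PRE observables plus the stored generating Γ2 profiles."""

    table: pd.DataFrame          # site, chain, residue, ratio, true_ratio
    gamma2: dict[str, np.ndarray]  # site name -> (n_residues, n_frames)
    residues: np.ndarray
    true_gamma2_avg: dict[str, np.ndarray]


def synthesize_pre(
    ensemble: Ensemble,
    sites: list[SpinLabelSite],
    truth: GroundTruth,
    constants: PhysicalConstants | None = None,
    target_chain: str = "A",
    n_rotamers: int = 16,
) -> SyntheticPRE:
    """Generate a synthetic experimental PRE table from ground-truth weights.

    Per residue and site the intensity ratio is the forward model applied to
    the ground-truth-weighted Γ2, multiplied by multiplicative Gaussian noise
    of sd ``truth.noise_sd`` and clipped to [0, 1.2].  With zero noise the
    table is an exact fixed point of the forward model.
    """
    if constants is None:
        constants = PhysicalConstants()
    weights = ensemble.true_weights
    if weights is None:
        weights = ensemble.prior_weights
    rng = np.random.default_rng(truth.seed + 1)
    residues = ensemble.residue_map(target_chain).residue_numbers
    rows = []
    gamma2: dict[str, np.ndarray] = {}
    true_avg: dict[str, np.ndarray] = {}
    for k, site in enumerate(sites):
        mat = site_gamma2_matrix(
            ensemble, site, target_chain, constants,
            n_rotamers=n_rotamers, seed=truth.seed + 100 + k,
        )
        gamma2[site.name] = mat
        avg = gamma2_ensemble(mat, weights)
        true_avg[site.name] = avg
        true_ratio = gamma2_to_intensity(avg, constants)
        noisy = true_ratio
        if truth.noise_sd > 0:
            noisy = true_ratio * rng.normal(1.0, truth.noise_sd, size=len(avg))
        noisy = np.clip(noisy, 0.0, 1.2)
        rows.append(
            pd.DataFrame(
                {
                    "site": site.name,
                    "chain": target_chain,
                    "residue": residues,
                    "ratio": noisy,
                    "true_ratio": true_ratio,
                }
            )
        )
    return SyntheticPRE(
        table=pd.concat(rows, ignore_index=True),
        gamma2=gamma2,
        residues=residues,
        true_gamma2_avg=true_avg,
    )


def synthesize_titration(
    kd_true: dict[str, float],
    receptor_conc: float = 100.0,
    ligand_series: tuple[float, ...] = (10, 20, 40, 60, 80, 100, 150, 200, 300),
    noise_sd: float = 0.0,
    seed: int = 0,
    motif_residues: dict[str, list[int]] | None = None,
):
    """Synthetic per-residue titration intensity decays I/I0.

    ``I/I0 = 1 - fb(L; P, Kd)`` with fb from the quadratic single-site
    depletion binding model, plus multiplicative noise.  Concentration units
    are carried as entered (defaults are μM-scale).  Returns a
    :class:`idpre.titration.TitrationSeries`.
    """
    from .titration import TitrationSeries, fraction_bound

    series = np.asarray(ligand_series, dtype=float)
    if np.any(series <= 0):
        raise ValueError("ligand concentrations must be positive")
    if np.any(np.diff(series) <= 0):
        raise ValueError("ligand concentrations must be strictly increasing")
    if motif_residues is None:
        spec = ChainSpec()
        motif_residues = {
            m: list(range(s, e + 1))
            for m, (s, e) in spec.helical_segments.items()
            if m in kd_true
        }
    rng = np.random.default_rng(seed)
    rows = []
    for motif, kd in kd_true.items():
        for res in motif_residues[motif]:
            for lig in series:
                fb = fraction_bound(lig, receptor_conc, kd)
                ratio = 1.0 - fb
                if noise_sd > 0:
                    ratio = ratio * rng.normal(1.0, noise_sd)
                rows.append((res, motif, lig, max(ratio, 0.0)))
    df = pd.DataFrame(rows, columns=["residue", "motif", "ligand_conc", "ratio"])
    return TitrationSeries(
        receptor_conc=receptor_conc,
        data=df,
        motif_map={m: list(r) for m, r in motif_residues.items()},
    )
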