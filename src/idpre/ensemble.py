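"""Ensemble container and multi-model PDB / metadata I/O.

An :class:`Ensemble` holds the coordinates of one or more named chains over a
set of frames, together with a per-frame state label and a prior weight
:math:`w_j^0`.  Coordinates are stored in Å as ``(n_frames, n_atoms, 3)``
arrays per chain.  Coarse-grained chains carry one bead ("CA") per residue;
all-atom-backbone chains carry repeating ``N, CA, C`` triples.  Native author
residue numbering is preserved end-to-end (e.g. a receptor numbered 892–1051);
:class:`ResidueMap` provides the bijection to 0-based analysis indices.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

__all__ = ["Ensemble", "ResidueMap", "read_ensemble", "write_ensemble"]


class EnsembleError(ValueError):
    """Raised for topology or metadata inconsistencies."""


@dataclass
class ResidueMap:
    """Bijective mapping between native residue numbers and 0-based indices."""

    chain_id: str
    residue_numbers: np.ndarray  # native numbering, one entry per residue

    def __post_init__(self) -> None:
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        if len(np.unique(self.residue_numbers)) != len(self.residue_numbers):
            raise EnsembleError(
                f"chain {self.chain_id}: residue numbering is not bijective"
            )
        self._to_index = {int(r): i for i, r in enumerate(self.residue_numbers)}

    def index(self, residue_number: int) -> int:
        try:
            return self._to_index[int(residue_number)]
        except KeyError:
            raise EnsembleError(
                f"residue {residue_number} not in chain {self.chain_id}"
            ) from None

    def number(self, index: int) -> int:
        return int(self.residue_numbers[index])

    def __len__(self) -> int:
        return len(self.residue_numbers)


@dataclass
class Ensemble:
    """Frames of coordinates for named chains with states and prior weights.

    Parameters
    ----------
    chains
        Mapping chain id -> coordinates ``(n_frames, n_atoms, 3)`` in Å.
    residue_numbers
        Mapping chain id -> native residue number per *atom*.
    atom_names
        Mapping chain id -> atom name per atom (default all ``"CA"``).
    states
        Per-frame state label (default a single state ``"I"``).
    prior_weights
        Per-frame prior weight ``w_j^0``; uniform when omitted.
    true_weights
        Optional ground-truth frame weights (synthetic ensembles only).
    """

    chains: dict[str, np.ndarray]
    residue_numbers: dict[str, np.ndarray] | None = None
    atom_names: dict[str, np.ndarray] | None = None
    states: np.ndarray | None = None
    prior_weights: np.ndarray | None = None
    true_weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.chains:
            raise EnsembleError("ensemble has no chains")
        n_frames = {c: np.asarray(x).shape[0] for c, x in self.chains.items()}
        if len(set(n_frames.values())) != 1:
            raise EnsembleError(f"chains disagree on frame count: {n_frames}")
        self.chains = {c: np.asarray(x, dtype=float) for c, x in self.chains.items()}
        nf = self.n_frames
        if self.residue_numbers is None:
            self.residue_numbers = {
                c: np.arange(1, x.shape[1] + 1) for c, x in self.chains.items()
            }
        self.residue_numbers = {
            c: np.asarray(v, dtype=int) for c, v in self.residue_numbers.items()
        }
        if self.atom_names is None:
            self.atom_names = {
                c: np.array(["CA"] * x.shape[1]) for c, x in self.chains.items()
            }
        for c, x in self.chains.items():
            if len(self.residue_numbers[c]) != x.shape[1]:
                raise EnsembleError(f"chain {c}: residue numbering length mismatch")
            if len(self.atom_names[c]) != x.shape[1]:
                raise EnsembleError(f"chain {c}: atom name length mismatch")
        if self.states is None:
            self.states = np.array(["I"] * nf, dtype=object)
        else:
            self.states = np.asarray(self.states, dtype=object)
            if len(self.states) != nf:
                raise EnsembleError(
                    f"{len(self.states)} state labels for {nf} frames"
                )
        if self.prior_weights is None:
            self.prior_weights = np.full(nf, 1.0 / nf)
        else:
            self.prior_weights = np.asarray(self.prior_weights, dtype=float)
            if len(self.prior_weights) != nf:
                raise EnsembleError(
                    f"{len(self.prior_weights)} prior weights for {nf} frames"
                )
            if np.any(self.prior_weights < 0):
                raise EnsembleError("prior weights must be nonnegative")
            s = self.prior_weights.sum()
            if not np.isclose(s, 1.0):
                if s <= 0:
                    raise EnsembleError("prior weights sum to zero")
                self.prior_weights = self.prior_weights / s
        if self.true_weights is not None:
            self.true_weights = np.asarray(self.true_weights, dtype=float)
            if len(self.true_weights) != nf:
                raise EnsembleError("true_weights length mismatch")

    @property
    def n_frames(self) -> int:
        return next(iter(self.chains.values())).shape[0]

    @property
    def chain_ids(self) -> list[str]:
        return list(self.chains)

    def residue_map(self, chain: str) -> ResidueMap:
        mask = self.atom_names[chain] == "CA"
        return ResidueMap(chain, self.residue_numbers[chain][mask])

    def ca_coords(self, chain: str) -> np.ndarray:
        """Cα (bead) coordinates ``(n_frames, n_residues, 3)`` for a chain."""
        mask = self.atom_names[chain] == "CA"
        return self.chains[chain][:, mask, :]

    def subset(self, frame_idx: np.ndarray) -> "Ensemble":
        frame_idx = np.asarray(frame_idx)
        return Ensemble(
            chains={c: x[frame_idx] for c, x in self.chains.items()},
            residue_numbers={c: v.copy() for c, v in self.residue_numbers.items()},
            atom_names={c: v.copy() for c, v in self.atom_names.items()},
            states=self.states[frame_idx],
            prior_weights=None,
            true_weights=(
                None if self.true_weights is None else self.true_weights[frame_idx]
            ),
        )


def _to_atom_array_stack(ens: Ensemble) -> struc.AtomArrayStack:
    n_atoms = sum(x.shape[1] for x in ens.chains.values())
    stack = struc.AtomArrayStack(ens.n_frames, n_atoms)
    coords = np.concatenate([ens.chains[c] for c in ens.chain_ids], axis=1)
    stack.coord = coords
    stack.chain_id = np.concatenate(
        [[c] * ens.chains[c].shape[1] for c in ens.chain_ids]
    )
    stack.res_id = np.concatenate([ens.residue_numbers[c] for c in ens.chain_ids])
    stack.atom_name = np.concatenate([ens.atom_names[c] for c in ens.chain_ids])
    stack.res_name = np.array(["ALA"] * n_atoms)
    stack.element = np.array(
        [name[0] for name in stack.atom_name]
    )
    stack.hetero = np.zeros(n_atoms, dtype=bool)
    return stack


def write_ensemble(ens: Ensemble, pdb_path: str | Path,
                   metadata_path: str | Path | None = None) -> None:
    """Write a multi-model PDB (one MODEL per frame) plus frame metadata CSV.

    The metadata table has columns ``frame, state, prior_weight`` and, for
    synthetic ensembles, ``true_weight``.
    """
    if ens.n_frames == 0:
        raise EnsembleError("cannot write an empty ensemble")
    pdb_path = Path(pdb_path)
    f = PDBFile()
    f.set_structure(_to_atom_array_stack(ens))
    f.write(str(pdb_path))
    if metadata_path is None:
        metadata_path = pdb_path.with_suffix(".meta.csv")
    meta = pd.DataFrame(
        {
            "frame": np.arange(ens.n_frames),
            "state": ens.states,
            "prior_weight": ens.prior_weights,
        }
    )
    if ens.true_weights is not None:
        meta["true_weight"] = ens.true_weights
    meta.to_csv(metadata_path, index=False)


def read_ensemble(pdb_path: str | Path,
                  metadata_path: str | Path | None = None) -> Ensemble:
    """Read an ensemble written by :func:`write_ensemble`.

    Without a metadata table the ensemble gets uniform priors and a single
    state.  A metadata row count that disagrees with the number of PDB models
    is an error.
    """
    pdb_path = Path(pdb_path)
    f = PDBFile.read(str(pdb_path))
    stack = f.get_structure(model=None)
    if not isinstance(stack, struc.AtomArrayStack):
        stack = struc.stack([stack])
    chains: dict[str, np.ndarray] = {}
    residue_numbers: dict[str, np.ndarray] = {}
    atom_names: dict[str, np.ndarray] = {}
    for cid in np.unique(stack.chain_id):
        mask = stack.chain_id == cid
        chains[str(cid)] = stack.coord[:, mask, :]
        residue_numbers[str(cid)] = stack.res_id[mask]
        atom_names[str(cid)] = stack.atom_name[mask]
    states = prior = true_w = None
    if metadata_path is None:
        candidate = pdb_path.with_suffix(".meta.csv")
        metadata_path = candidate if candidate.exists() else None
    if metadata_path is not None:
        meta = pd.read_csv(metadata_path)
        nf = stack.coord.shape[0]
        if len(meta) != nf:
            raise EnsembleError(
                f"metadata has {len(meta)} rows but PDB has {nf} models"
            )
        states = meta["state"].to_numpy()
        prior = meta["prior_weight"].to_numpy()
        if "true_weight" in meta.columns:
            true_w = meta["true_weight"].to_numpy()
    return Ensemble(
        chains=chains,
        residue_numbers=residue_numbers,
        atom_names=atom_names,
        states=states,
        prior_weights=prior,
        true_weights=true_w,
    )
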