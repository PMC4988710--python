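"""Coarse-grained bead containers.

A :class:`ChainModel` holds one bead per residue (C-alpha for protein chains,
one bead per nucleotide for DNA strands).  A :class:`BeadSystem` is an ordered
collection of chains sharing one coordinate frame; restraints reference beads
by ``(chain_id, residue_number)`` and are resolved against a system before
evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, NamedTuple, Optional, Tuple

import numpy as np

BOND_LENGTH = 3.8  # target consecutive C-alpha distance, Angstrom
BOND_MIN, BOND_MAX = 2.8, 4.8  # acceptable range after refinement
HARD_CLASH = 2.5  # cross-chain bead pairs closer than this are clashes


class BeadId(NamedTuple):
    """Identifier of one bead: chain id plus residue number."""

    chain: str
    resid: int

    def __str__(self) -> str:  # used in violation reports and TSV rows
        return f"{self.chain}:{self.resid}"

    @classmethod
    def parse(cls, text: str) -> "BeadId":
        chain, resid = text.split(":")
        return cls(chain, int(resid))


@dataclass
class ChainModel:
    """One chain of beads, one bead per residue."""

    chain_id: str
    residue_numbers: np.ndarray  # int array, shape (n,)
    coords: np.ndarray  # float array, shape (n, 3)

    def __post_init__(self) -> None:
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.residue_numbers), 3):
            raise ValueError(
                f"chain {self.chain_id}: {len(self.residue_numbers)} residues "
                f"but coords shape {self.coords.shape}"
            )

    def __len__(self) -> int:
        return len(self.residue_numbers)

    def copy(self) -> "ChainModel":
        return ChainModel(self.chain_id, self.residue_numbers.copy(), self.coords.copy())

    def subset(self, residues: Iterable[int]) -> "ChainModel":
        wanted = set(residues)
        mask = np.array([r in wanted for r in self.residue_numbers])
        return ChainModel(self.chain_id, self.residue_numbers[mask], self.coords[mask])

    def bead_coord(self, resid: int) -> np.ndarray:
        idx = np.where(self.residue_numbers == resid)[0]
        if len(idx) == 0:
            raise KeyError(f"residue {resid} not in chain {self.chain_id}")
        return self.coords[idx[0]]


@dataclass
class BeadSystem:
    """Several chains sharing one coordinate system."""

    chains: Dict[str, ChainModel] = field(default_factory=dict)

    @classmethod
    def from_chains(cls, chains: Iterable[ChainModel]) -> "BeadSystem":
        sys = cls()
        for c in chains:
            sys.add(c)
        return sys

    def add(self, chain: ChainModel) -> None:
        if chain.chain_id in self.chains:
            raise ValueError(f"duplicate chain id {chain.chain_id!r}")
        self.chains[chain.chain_id] = chain

    def copy(self) -> "BeadSystem":
        return BeadSystem({cid: c.copy() for cid, c in self.chains.items()})

    # -- flat views -------------------------------------------------------
    def flatten(self) -> Tuple[np.ndarray, List[BeadId], Dict[BeadId, int]]:
        """Concatenated coords, bead ids in order, and id -> flat index map."""
        coords = []
        ids: List[BeadId] = []
        for cid, chain in self.chains.items():
            coords.append(chain.coords)
            ids.extend(BeadId(cid, int(r)) for r in chain.residue_numbers)
        flat = np.concatenate(coords) if coords else np.zeros((0, 3))
        index = {bid: i for i, bid in enumerate(ids)}
        return flat, ids, index

    def set_flat_coords(self, flat: np.ndarray) -> None:
        """Write a flat coordinate array (same ordering as :meth:`flatten`) back."""
        pos = 0
        for chain in self.chains.values():
            n = len(chain)
            chain.coords = np.array(flat[pos : pos + n], dtype=float)
            pos += n

    def resolve(self, bead: BeadId) -> np.ndarray:
        try:
            return self.chains[bead.chain].bead_coord(bead.resid)
        except KeyError as exc:
            raise KeyError(f"bead {bead} not resolvable in system") from exc

    def clash_count(self, threshold: float = HARD_CLASH) -> int:
        """Number of cross-chain bead pairs closer than ``threshold``."""
        from scipy.spatial.distance import cdist

        cids = list(self.chains)
        count = 0
        for i, a in enumerate(cids):
            for b in cids[i + 1 :]:
                d = cdist(self.chains[a].coords, self.chains[b].coords)
                count += int((d < threshold).sum())
        return count
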