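"""File formats and run configuration.

Coarse bead models travel as PDB (one pseudo-atom per bead: CA for protein
residues, P for nucleotides; chains keep their ids and residue numbering), so
models open directly in standard structure viewers.  Sequences come in as
FASTA, titration tables as CSV/TSV with columns ``conc_nM`` and
``bound_fraction``, restraint sets as the TSV dialect defined in
:mod:`soxdimer.restraints`.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, field_validator

from .core import BeadSystem, ChainModel
from .emsa import TitrationSeries

__all__ = [
    "read_fasta",
    "read_titration_table",
    "read_pdb",
    "write_pdb",
    "RunConfig",
]

PROTEIN_CHAINS = {"A", "B"}


def read_fasta(path: Union[str, Path]) -> List[Tuple[str, str]]:
    """(name, sequence) pairs from a FASTA file."""
    from Bio import SeqIO

    records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def read_titration_table(path: Union[str, Path], dna_conc: float = 9.0) -> TitrationSeries:
    """Read a titration table (CSV or TSV) into a TitrationSeries.

    Expects columns ``conc_nM`` and ``bound_fraction``.
    """
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    missing = {"conc_nM", "bound_fraction"} - set(df.columns)
    if missing:
        raise ValueError(f"titration table missing column(s) {sorted(missing)}")
    return TitrationSeries(
        df["conc_nM"].to_numpy(float),
        df["bound_fraction"].to_numpy(float),
        dna_conc=dna_conc,
        label=str(path),
    )


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def _to_atom_array(system: BeadSystem):
    import biotite.structure as struc

    n = sum(len(c) for c in system.chains.values())
    arr = struc.AtomArray(n)
    pos = 0
    coords = np.zeros((n, 3))
    for cid, chain in system.chains.items():
        m = len(chain)
        sl = slice(pos, pos + m)
        coords[sl] = chain.coords
        arr.chain_id[sl] = cid
        arr.res_id[sl] = chain.residue_numbers
        if cid in PROTEIN_CHAINS:
            arr.atom_name[sl] = "CA"
            arr.res_name[sl] = "ALA"
            arr.element[sl] = "C"
        else:
            arr.atom_name[sl] = "P"
            arr.res_name[sl] = "DN"
            arr.element[sl] = "P"
        arr.hetero[sl] = False
        pos += m
    arr.coord = coords
    return arr


def write_pdb(
    models: Union[BeadSystem, Sequence[BeadSystem]],
    path: Union[str, Path],
) -> None:
    """Write one system (or an ensemble) as (multi-MODEL) PDB."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    if isinstance(models, BeadSystem):
        stack_or_array = _to_atom_array(models)
    else:
        arrays = [_to_atom_array(m) for m in models]
        stack_or_array = struc.stack(arrays)
    pdb = PDBFile()
    pdb.set_structure(stack_or_array)
    pdb.write(str(path))


def read_pdb(path: Union[str, Path]) -> List[BeadSystem]:
    """Read coarse bead systems from a PDB file (one per MODEL).

    Keeps one bead per residue: the CA atom for protein residues, the P atom
    for nucleotides (falling back to the first atom of a residue when neither
    is present, so all-atom files collapse to a usable coarse model).
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    try:
        pdb = PDBFile.read(str(path))
        stack = pdb.get_structure()
    except Exception as exc:
        raise ValueError(f"cannot parse PDB file {path}: {exc}") from exc
    systems: List[BeadSystem] = []
    for model_idx in range(stack.stack_depth()):
        arr = stack[model_idx]
        keep = np.isin(arr.atom_name, ("CA", "P"))
        sel = arr[keep]
        if len(sel) == 0:
            raise ValueError(f"{path}: no CA or P beads found in model {model_idx + 1}")
        system = BeadSystem()
        for cid in np.unique(sel.chain_id):
            mask = sel.chain_id == cid
            system.add(
                ChainModel(str(cid), sel.res_id[mask].astype(int), sel.coord[mask])
            )
        systems.append(system)
    return systems


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

class RunConfig(BaseModel):
    """Flat, validated assembly run configuration.

    Mirrors :class:`soxdimer.assembly.AssemblyConfig`; unknown keys are
    rejected so typos fail before any computation.  Load from a flat YAML
    key-value file with :meth:`from_file`.
    """

    model_config = ConfigDict(extra="forbid")

    probe_top_strand: str = ""
    motif: str = "CACAAAG"
    per_site_bend: float = 54.0
    coplanar_bend: bool = True
    n_dock_trials: int = 400
    dock_top: int = 20
    n_contact_restraints: int = 50
    contact_cutoff: float = 10.0
    cis_dimerization: bool = False
    seed: int = 0
    out_model: str = "model.pdb"
    out_report: str = "report.json"

    @field_validator("probe_top_strand")
    @classmethod
    def _probe_ok(cls, v: str) -> str:
        bad = set(v.upper()) - set("ACGT")
        if v and bad:
            raise ValueError(f"invalid probe bases {sorted(bad)}")
        return v.upper()

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config {path} must be a flat key: value mapping")
        for key, value in data.items():
            if isinstance(value, (dict, list)):
                raise ValueError(f"config key {key!r} is nested; the format is flat")
        return cls(**data)

    def to_assembly_config(self):
        from .assembly import AssemblyConfig
        from .synthetic_data import CC36_SEQUENCE

        return AssemblyConfig(
            probe_top_strand=self.probe_top_strand or CC36_SEQUENCE,
            motif=self.motif,
            per_site_bend=self.per_site_bend,
            coplanar_bend=self.coplanar_bend,
            n_dock_trials=self.n_dock_trials,
            dock_top=self.dock_top,
            n_contact_restraints=self.n_contact_restraints,
            contact_cutoff=self.contact_cutoff,
            cis_dimerization=self.cis_dimerization,
            seed=self.seed,
        )
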