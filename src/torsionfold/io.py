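"""File I/O: FASTA sequences, PDB models, config files, run manifests.

Residue numbering is 1-based in PDB files and user messages; all
internal indices and the DFR restraint container are 0-based.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass

import numpy as np
from Bio import SeqIO
from Bio.PDB import PDBParser

from torsionfold import geometry as geom
from torsionfold.energy import DEFAULT_WEIGHTS, WEIGHT_NAMES, WeightVector
from torsionfold.geometry import AMINO_ACIDS, CA, CB, C, H, N, O, SC

# three-letter <-> one-letter residue codes
THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


class FastaError(ValueError):
    pass


class PdbError(ValueError):
    pass


class ConfigError(ValueError):
    pass


def read_fasta(path) -> str:
    """Single-record FASTA -> validated uppercase sequence."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) == 0:
        raise FastaError(f"{path}: no FASTA records found")
    if len(records) > 1:
        raise FastaError(f"{path}: expected a single record, found {len(records)}")
    seq = str(records[0].seq).upper()
    for pos, aa in enumerate(seq, start=1):
        if aa not in AMINO_ACIDS:
            raise FastaError(
                f"{path}: invalid residue letter {aa!r} at position {pos}"
            )
    return seq


# ---------------------------------------------------------------------------
# PDB

_PDB_SLOTS = [(N, "N"), (CA, "CA"), (C, "C"), (O, "O"), (CB, "CB")]


def write_pdb(model: geom.ProteinModel, path, include_h: bool = False,
              include_sc: bool = False) -> None:
    """Write backbone + CB ATOM records (chain A, 1-based numbering).

    The side-chain center is a pseudo-atom; it is emitted (as atom name
    ``SC``) only in the optional debug dialect.
    """
    slots = list(_PDB_SLOTS)
    if include_h:
        slots.insert(1, (H, "H"))
    if include_sc:
        slots.append((SC, "SC"))
    serial = 1
    with open(path, "w") as fh:
        for i, aa in enumerate(model.sequence):
            res3 = ONE_TO_THREE[aa]
            for slot, name in slots:
                if aa == "G" and slot in (CB, SC):
                    continue
                x, y, z = model.coords[i, slot]
                nm = f" {name:<3s}" if len(name) < 4 else name
                element = name[0] if name != "SC" else "X"
                fh.write(
                    f"ATOM  {serial:5d} {nm} {res3} A{i + 1:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          "
                    f"{element:>2s}\n"
                )
                serial += 1
        fh.write("END\n")


def read_pdb(path) -> geom.ProteinModel:
    """Read a single-chain PDB into a model (coordinates + torsions).

    Takes the first altloc of each atom (with a warning), rebuilds a
    missing CB from the backbone, and errors listing any residues whose
    N/CA/C backbone is incomplete.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("model", str(path))
    chains = [c for mdl in structure for c in mdl]
    if not chains:
        raise PdbError(f"{path}: no chains found")
    chain = chains[0]
    residues = [r for r in chain if r.id[0] == " "]
    if not residues:
        raise PdbError(f"{path}: no standard residues in chain {chain.id}")
    L = len(residues)
    seq = []
    coords = np.zeros((L, 7, 3))
    missing = []
    saw_altloc = False
    for i, res in enumerate(residues):
        aa = THREE_TO_ONE.get(res.get_resname())
        if aa is None:
            raise PdbError(
                f"{path}: non-standard residue {res.get_resname()} at "
                f"position {res.id[1]}"
            )
        seq.append(aa)
        present = {}
        for atom in res:
            if atom.is_disordered():
                saw_altloc = True
                atom = atom.disordered_get_list()[0]
            present[atom.get_name()] = atom.get_coord()
        for name in ("N", "CA", "C"):
            if name not in present:
                missing.append(f"{res.get_resname()}{res.id[1]} ({name})")
        if missing:
            continue
        coords[i, N] = present["N"]
        coords[i, CA] = present["CA"]
        coords[i, C] = present["C"]
        if "O" in present:
            coords[i, O] = present["O"]
        if aa != "G" and "CB" in present:
            coords[i, CB] = present["CB"]
    if missing:
        raise PdbError(
            f"{path}: incomplete backbone for residues: " + ", ".join(missing)
        )
    if saw_altloc:
        warnings.warn(f"{path}: alternate locations present; first taken")
    sequence = "".join(seq)
    phi, psi = geom.compute_torsions(coords)
    model = geom.ProteinModel(sequence=sequence, phi=phi, psi=psi, coords=coords)
    # rebuild pseudo-atoms (H, SC, any missing O/CB) with ideal geometry
    geom.place_pseudo_atoms(model)
    # restore observed O/CB where the file provided them
    for i, res in enumerate(residues):
        names = {
            (a.disordered_get_list()[0] if a.is_disordered() else a).get_name():
            (a.disordered_get_list()[0] if a.is_disordered() else a).get_coord()
            for a in res
        }
        if "O" in names:
            coords[i, O] = names["O"]
        if seq[i] != "G" and "CB" in names:
            coords[i, CB] = names["CB"]
    return model


# ---------------------------------------------------------------------------
# config files: "key = value" lines grouped by blank lines / comments

def write_config(path, weights: WeightVector | None = None,
                 options: dict | None = None) -> None:
    weights = weights or WeightVector.default()
    with open(path, "w") as fh:
        fh.write("# torsionfold configuration\n")
        fh.write("# restraint-term weights by sequence-separation class\n")
        for name in WEIGHT_NAMES:
            fh.write(f"weight.{name} = {weights[name]}\n")
        if options:
            fh.write("\n# optimizer options\n")
            for key, value in options.items():
                fh.write(f"{key} = {value}\n")


def read_config(path):
    """Parse a key = value config; returns (WeightVector, options dict)."""
    wd = dict(DEFAULT_WEIGHTS)
    options = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (part.strip() for part in line.split("=", 1))
            if key.startswith("weight."):
                name = key[len("weight."):]
                if name not in WEIGHT_NAMES:
                    raise ConfigError(f"{path}:{lineno}: unknown weight {name!r}")
                wd[name] = float(value)
            else:
                options[key] = value
    return WeightVector.from_dict(wd), options


# ---------------------------------------------------------------------------
# run manifest

@dataclass
class RunManifest:
    """Everything needed to re-run a folding command bit-identically."""

    inputs: dict  # path -> sha256
    config: dict
    seed: int
    version: str
    termination: str
    energy: float
    n_steps: int

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)
            fh.write("\n")


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
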