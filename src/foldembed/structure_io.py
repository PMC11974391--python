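"""Reading protein domain structures from PDB/mmCIF files.

A *domain* is the unit of embedding and search: a compact region of a
single chain, possibly discontinuous (several residue ranges). Only the
Cα trace is required downstream; Cβ atoms and residue names are kept
when present because contact order needs them.

Conventions (SCOPe/Astral-style):

* residues are addressed by author numbering; insertion-coded residues
  are distinct and ordered as encountered in the file;
* for alternate locations the first-listed conformer is taken;
* only the first model of multi-model files is used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "DomainDefinition",
    "DomainStructure",
    "FormatError",
    "EmptyDomainError",
    "read_domain",
    "validate_domain",
    "parse_domain_spec",
]

#: training-set residue-count filter; validate_domain warns outside it
MIN_DOMAIN_LENGTH = 20
MAX_DOMAIN_LENGTH = 500


class FormatError(ValueError):
    """The file could not be parsed as PDB or mmCIF."""


class EmptyDomainError(ValueError):
    """The definition selected no residues with Cα atoms."""


@dataclass(frozen=True)
class DomainDefinition:
    """Which residues of which chain constitute the domain.

    ``segments`` are inclusive ``(start, end)`` ranges in author residue
    numbering. Multiple segments describe discontinuous domains.
    """

    source_path: str
    chain_id: str
    segments: tuple[tuple[int, int], ...]
    name: str = ""

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("segments must be non-empty")
        for start, end in self.segments:
            if start > end:
                raise ValueError(f"segment start {start} > end {end}")
        spans = sorted(self.segments)
        for (_, e1), (s2, _) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError("segments must not overlap")


@dataclass
class DomainStructure:
    """Ordered Cα trace of one domain, with optional Cβ/residue names."""

    name: str
    ca_coords: np.ndarray  # (L, 3) Å
    residue_numbers: np.ndarray  # (L,) int author numbering
    cb_coords: Optional[np.ndarray] = None  # (L, 3), NaN rows where absent
    residue_names: Optional[list[str]] = None
    insertion_codes: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.ca_coords = np.asarray(self.ca_coords, dtype=float)
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        if self.ca_coords.ndim != 2 or self.ca_coords.shape[1] != 3:
            raise ValueError("ca_coords must have shape (L, 3)")
        if len(self.residue_numbers) != len(self.ca_coords):
            raise ValueError("residue_numbers length mismatch")
        if not np.all(np.isfinite(self.ca_coords)):
            raise ValueError("ca_coords must be finite")
        if self.cb_coords is not None:
            self.cb_coords = np.asarray(self.cb_coords, dtype=float)
            if self.cb_coords.shape != self.ca_coords.shape:
                raise ValueError("cb_coords shape mismatch")

    @property
    def L(self) -> int:
        return len(self.ca_coords)

    def contact_atoms(self) -> np.ndarray:
        """Cβ coordinates with Cα substituted where Cβ is absent (glycine,
        incomplete models)."""
        if self.cb_coords is None:
            return self.ca_coords.copy()
        atoms = self.cb_coords.copy()
        missing = ~np.all(np.isfinite(atoms), axis=1)
        atoms[missing] = self.ca_coords[missing]
        return atoms


def _read_structure(path: str | Path) -> gemmi.Structure:
    path = Path(path)
    suffix = path.suffix.lower()
    try:
        if suffix in {".cif", ".mmcif"}:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        elif suffix in {".pdb", ".ent"}:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
        else:
            # sniff: mmCIF files start with a data_ block
            head = path.read_bytes()[:2048]
            fmt = (
                gemmi.CoorFormat.Mmcif
                if head.lstrip().startswith(b"data_")
                else gemmi.CoorFormat.Pdb
            )
            st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError, OSError) as exc:
        raise FormatError(f"cannot parse structure file {path}: {exc}") from exc
    if len(st) == 0 or len(st[0]) == 0:
        raise FormatError(f"no coordinate content parsed from {path}")
    return st


def _first_atom(residue: gemmi.Residue, name: str) -> Optional[gemmi.Atom]:
    """First-listed atom with the given name (first altloc wins)."""
    for atom in residue:
        if atom.name == name:
            return atom
    return None


def read_domain(path: str | Path, definition: DomainDefinition) -> DomainStructure:
    """Extract the Cα trace for ``definition`` from a PDB/mmCIF file.

    Residues are returned in segment-then-file order. Residues lacking a
    Cα atom are skipped with a logged warning. Cβ coordinates are
    recorded where present (NaN rows otherwise).

    Raises
    ------
    FormatError
        if the file cannot be parsed.
    EmptyDomainError
        if the definition selects no residues with Cα atoms.
    """
    st = _read_structure(path)
    model = st[0]
    chain = model.find_chain(definition.chain_id)
    if chain is None:
        raise EmptyDomainError(
            f"chain {definition.chain_id!r} not found in {path}"
        )

    ca, cb, nums, names, icodes = [], [], [], [], []
    for start, end in definition.segments:
        for residue in chain:
            num = residue.seqid.num
            if num < start or num > end:
                continue
            atom_ca = _first_atom(residue, "CA")
            if atom_ca is None:
                info = gemmi.find_tabulated_residue(residue.name)
                if (info and info.is_amino_acid()) or _first_atom(residue, "CB"):
                    logger.warning(
                        "residue %s%s %s in %s has no CA atom; skipped",
                        num,
                        residue.seqid.icode.strip(),
                        residue.name,
                        definition.name or path,
                    )
                continue
            atom_cb = _first_atom(residue, "CB")
            ca.append([atom_ca.pos.x, atom_ca.pos.y, atom_ca.pos.z])
            cb.append(
                [atom_cb.pos.x, atom_cb.pos.y, atom_cb.pos.z]
                if atom_cb is not None
                else [np.nan] * 3
            )
            nums.append(num)
            names.append(residue.name)
            icodes.append(residue.seqid.icode.strip())

    if not ca:
        raise EmptyDomainError(
            f"definition {definition.name or definition.segments} selected "
            f"no residues with CA atoms in {path}"
        )
    return DomainStructure(
        name=definition.name or Path(path).stem,
        ca_coords=np.array(ca),
        residue_numbers=np.array(nums),
        cb_coords=np.array(cb),
        residue_names=names,
        insertion_codes=icodes,
    )


def validate_domain(structure: DomainStructure) -> list[str]:
    """Warn (never fail) when the domain falls outside the 20–500 residue
    band used to filter the training set; searching with such domains is
    still permitted."""
    warnings_: list[str] = []
    if structure.L < MIN_DOMAIN_LENGTH:
        warnings_.append(
            f"domain {structure.name} has {structure.L} residues "
            f"(< {MIN_DOMAIN_LENGTH}); embeddings may be unreliable"
        )
    if structure.L > MAX_DOMAIN_LENGTH:
        warnings_.append(
            f"domain {structure.name} has {structure.L} residues "
            f"(> {MAX_DOMAIN_LENGTH}); embeddings may be unreliable"
        )
    for msg in warnings_:
        logger.warning(msg)
    return warnings_


def parse_domain_spec(spec: str, path: str | Path, name: str = "") -> DomainDefinition:
    """Parse ``CHAIN`` or ``CHAIN:START-END[,START-END...]`` into a
    :class:`DomainDefinition`. A bare chain id selects every residue."""
    spec = spec.strip()
    if ":" not in spec:
        return DomainDefinition(
            source_path=str(path),
            chain_id=spec,
            segments=((-(10**6), 10**6),),
            name=name,
        )
    chain_id, _, ranges = spec.partition(":")
    segments = []
    for part in ranges.split(","):
        start_s, sep, end_s = part.partition("-")
        if not sep:
            raise ValueError(f"bad segment {part!r}; expected START-END")
        segments.append((int(start_s), int(end_s)))
    return DomainDefinition(
        source_path=str(path),
        chain_id=chain_id,
        segments=tuple(segments),
        name=name,
    )
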