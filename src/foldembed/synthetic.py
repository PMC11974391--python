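"""Synthetic labeled domain families for training and benchmarking.

Real fold classifications group domains hierarchically: members of a
family are nearly identical structures, superfamilies collect related
families, folds collect superfamilies sharing a core topology. The
generator emulates that statistical structure with Cα traces only:

* one independent *fold template* per fold — a self-avoiding chain with
  the consecutive-Cα spacing of real backbones (3.8 Å);
* *superfamily* templates derived from the fold template, and *family*
  templates from the superfamily template, by moderate coordinate
  perturbations (2.0 and 1.5 Å by default);
* *family members* = family template + small Gaussian coordinate noise
  (0.5 Å by default).

Within-family geometric spread is therefore much smaller than
between-family spread — the separability the contrastive objective
requires — while different folds are unrelated chains. The traces are
not physically realistic proteins (no side chains, no secondary
structure mix, perturbed copies slightly violate bond geometry) and
carry no sequence signal whatsoever.

All randomness flows from a single seed, so a spec generates the same
dataset bytes every time.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import DomainStructure
from .training import ClassificationLabel, LabeledDomain

__all__ = [
    "SyntheticSpec",
    "SyntheticDataset",
    "generate_template",
    "generate_hierarchy",
    "write_fixture_pdb",
    "write_fixture_set",
    "kabsch_rmsd",
]

CA_SPACING = 3.8  # Å, consecutive Cα distance
CLASH_DISTANCE = 3.0  # Å, excluded-volume threshold for non-consecutive pairs
HELIX_RADIUS = 2.3  # Å, ideal α-helix Cα radius
HELIX_RISE = 1.5  # Å per residue
HELIX_TWIST = np.deg2rad(100.0)  # per residue


@dataclass(frozen=True)
class SyntheticSpec:
    """Shape and noise scales of the generated hierarchy."""

    n_classes: int = 2
    n_folds_per_class: int = 2
    n_superfamilies_per_fold: int = 2
    n_families_per_superfamily: int = 2
    members_per_family: int = 6
    length_range: tuple[int, int] = (40, 100)
    within_family_noise: float = 0.5  # Å std per coordinate component
    family_perturbation: float = 1.5  # Å std, superfamily → family template
    superfamily_perturbation: float = 2.0  # Å std, fold → superfamily template
    seed: int = 0

    def __post_init__(self) -> None:
        if self.members_per_family < 2:
            raise ValueError("members_per_family must be >= 2")
        lo, hi = self.length_range
        if not (20 <= lo <= hi <= 500):
            raise ValueError("length_range must lie within [20, 500]")

    @property
    def n_families(self) -> int:
        return (
            self.n_classes
            * self.n_folds_per_class
            * self.n_superfamilies_per_fold
            * self.n_families_per_superfamily
        )


@dataclass
class SyntheticDataset:
    domains: list[LabeledDomain]
    spec: SyntheticSpec

    def split_by_family(
        self,
        fractions: tuple[float, float, float] = (0.75, 0.25, 0.0),
        rng: np.random.Generator | None = None,
    ) -> tuple[list[LabeledDomain], list[LabeledDomain], list[LabeledDomain]]:
        """Train/validation/test split with no family shared between
        splits."""
        rng = rng or np.random.default_rng(self.spec.seed + 1)
        keys = sorted({d.label.family_key() for d in self.domains})
        perm = rng.permutation(len(keys))
        n_train = max(1, round(fractions[0] * len(keys)))
        n_val = max(1, round(fractions[1] * len(keys)))
        groups = (
            {keys[i] for i in perm[:n_train]},
            {keys[i] for i in perm[n_train : n_train + n_val]},
            {keys[i] for i in perm[n_train + n_val :]},
        )
        return tuple(
            [d for d in self.domains if d.label.family_key() in g] for g in groups
        )


# ---- templates ---------------------------------------------------------


def helix_pair_distance(separation: int) -> float:
    """Closed-form Cα(i)–Cα(i+separation) distance on the ideal helix
    used by the generator: rise² plus the chord of the swept twist."""
    chord = 2.0 * HELIX_RADIUS * abs(np.sin(separation * HELIX_TWIST / 2.0))
    return float(np.hypot(separation * HELIX_RISE, chord))


def _helix_template(length: int) -> np.ndarray:
    t = np.arange(length)
    return np.column_stack(
        [
            HELIX_RADIUS * np.cos(t * HELIX_TWIST),
            HELIX_RADIUS * np.sin(t * HELIX_TWIST),
            HELIX_RISE * t,
        ]
    )


def _strand_template(length: int) -> np.ndarray:
    # extended zigzag; step length CA_SPACING with alternating lateral offset
    rise = 3.3
    lateral = np.sqrt(CA_SPACING**2 - rise**2) / 2.0
    t = np.arange(length)
    return np.column_stack(
        [rise * t, lateral * (-1.0) ** t, np.zeros(length)]
    )


def _random_walk_template(rng: np.random.Generator, length: int) -> np.ndarray:
    """Persistent self-avoiding walk with fixed 3.8 Å steps; a step that
    clashes (< 3 Å to any earlier non-consecutive Cα) is resampled, with
    backtracking when a dead end is reached."""
    coords = [np.zeros(3)]
    direction = _random_unit(rng)
    persistence = 0.7
    max_tries = 60
    while len(coords) < length:
        placed = False
        for _ in range(max_tries):
            proposal = direction + persistence * _random_unit(rng)
            norm = np.linalg.norm(proposal)
            if norm < 1e-9:
                continue
            step_dir = proposal / norm
            candidate = coords[-1] + CA_SPACING * step_dir
            if _clashes(candidate, coords[:-1]):
                continue
            coords.append(candidate)
            direction = step_dir
            placed = True
            break
        if not placed:
            # dead end: drop the last point and try again from there
            if len(coords) > 1:
                coords.pop()
            direction = _random_unit(rng)
    return np.array(coords)


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _clashes(candidate: np.ndarray, others: list[np.ndarray]) -> bool:
    if not others:
        return False
    d = np.linalg.norm(np.array(others) - candidate, axis=1)
    return bool(np.any(d < CLASH_DISTANCE))


def generate_template(
    rng: np.random.Generator, length: int, style: str = "random-walk"
) -> np.ndarray:
    """A (length, 3) Cα trace with consecutive spacing 3.8 Å and no
    non-consecutive pair closer than 3 Å.

    Styles: ``helix`` (ideal α-helix geometry), ``strand`` (extended
    zigzag), ``random-walk`` (persistent self-avoiding walk; the default
    for fold templates because independent draws are structurally
    unrelated)."""
    if length < 20:
        raise ValueError("templates must have >= 20 residues")
    if style in {"helix", "helix-like"}:
        return _helix_template(length)
    if style in {"strand", "strand-like"}:
        return _strand_template(length)
    if style in {"random-walk", "random-walk-with-excluded-volume"}:
        return _random_walk_template(rng, length)
    raise ValueError(f"unknown template style {style!r}")


# ---- hierarchy ---------------------------------------------------------


def _make_structure(name: str, coords: np.ndarray) -> DomainStructure:
    return DomainStructure(
        name=name,
        ca_coords=coords,
        residue_numbers=np.arange(1, len(coords) + 1),
        residue_names=["ALA"] * len(coords),
    )


def generate_hierarchy(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate the labeled domain set described by ``spec``.

    Labels follow the sccs convention: classes are letters, the other
    levels 1-based integers (e.g. ``a.2.1.2``). Deterministic in
    ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    domains: list[LabeledDomain] = []
    class_letters = string.ascii_lowercase
    if spec.n_classes > len(class_letters):
        raise ValueError("too many classes for letter labels")
    for ci in range(spec.n_classes):
        for fi in range(spec.n_folds_per_class):
            length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
            fold_template = generate_template(rng, length, "random-walk")
            for si in range(spec.n_superfamilies_per_fold):
                sf_template = fold_template + rng.normal(
                    0.0, spec.superfamily_perturbation, fold_template.shape
                )
                for mi in range(spec.n_families_per_superfamily):
                    fam_template = sf_template + rng.normal(
                        0.0, spec.family_perturbation, sf_template.shape
                    )
                    label = ClassificationLabel(
                        class_id=class_letters[ci],
                        fold_id=str(fi + 1),
                        superfamily_id=str(si + 1),
                        family_id=str(mi + 1),
                    )
                    for k in range(spec.members_per_family):
                        coords = fam_template + rng.normal(
                            0.0, spec.within_family_noise, fam_template.shape
                        )
                        name = f"d{label}_{k + 1}"
                        domains.append(
                            LabeledDomain(
                                domain_id=name,
                                structure=_make_structure(name, coords),
                                label=label,
                            )
                        )
    return SyntheticDataset(domains=domains, spec=spec)


# ---- fixtures on disk --------------------------------------------------


def write_fixture_pdb(structure: DomainStructure, path, chain_id: str = "A") -> None:
    """Minimal single-chain PDB rendering of a Cα (plus optional Cβ)
    trace, readable by :mod:`foldembed.structure_io`."""
    lines = []
    serial = 1
    names = structure.residue_names or ["ALA"] * structure.L
    for i in range(structure.L):
        x, y, z = structure.ca_coords[i]
        num = int(structure.residue_numbers[i])
        lines.append(
            f"ATOM  {serial:5d}  CA  {names[i]:>3s} {chain_id}{num:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
        serial += 1
        if structure.cb_coords is not None and np.all(
            np.isfinite(structure.cb_coords[i])
        ):
            bx, by, bz = structure.cb_coords[i]
            lines.append(
                f"ATOM  {serial:5d}  CB  {names[i]:>3s} {chain_id}{num:4d}    "
                f"{bx:8.3f}{by:8.3f}{bz:8.3f}  1.00  0.00           C"
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_fixture_set(dataset: SyntheticDataset, out_dir) -> Path:
    """Write every domain as a PDB fixture plus ``manifest.tsv``
    (domain_id, structure_path, chain/segment spec, label) and a
    ``classification.tsv`` (domain_id, label) usable by the CLI."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.tsv"
    classification = out_dir / "classification.tsv"
    with open(manifest, "w") as mf, open(classification, "w") as cf:
        mf.write("domain_id\tstructure_path\tchain_spec\tlabel\n")
        cf.write("domain_id\tlabel\n")
        for item in dataset.domains:
            pdb_path = out_dir / f"{item.domain_id}.pdb"
            write_fixture_pdb(item.structure, pdb_path)
            mf.write(f"{item.domain_id}\t{pdb_path.name}\tA\t{item.label}\n")
            cf.write(f"{item.domain_id}\t{item.label}\n")
    return manifest


# ---- geometry helper ---------------------------------------------------


def kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Cα RMSD of two equal-length traces after optimal superposition
    (Kabsch, proper rotation only)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("traces must have equal shape")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    h = ac.T @ bc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    diff = ac @ rot.T - bc
    return float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))
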