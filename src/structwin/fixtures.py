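"""Deterministic synthetic structures and coding-sequence alignments.

This generator stands in for real deposited structures and population
sequence samples so the whole pipeline is testable offline. A single seed
fully determines every output (structures, alignments, FASTA/PDB text).

Geometries
----------
``ideal-helix``
    Cα atoms on an idealised helix (1.5 Å rise, 100° twist, 2.3 Å radius)
    with four dummy side-chain atoms per residue pointing radially outward.
``random-coil``
    a 3.8 Å-step random walk of Cα positions.
``two-cluster``
    two compact blobs of residues with centers 50 Å apart (inter-cluster
    residue distances all exceed 15 Å by construction).

Mutation models
---------------
``none``
    all rows identical to the ancestral coding sequence.
``neutral-infinite-sites``
    each mutated codon's third position carries exactly one biallelic site;
    the derived allele count i is drawn from the neutral site-frequency
    spectrum, P(i) ∝ 1/i for i in 1..n−1, so π and θ_w have equal
    expectation and Tajima's D is centred near zero. The number of sites is
    Poisson with mean ``mutation_rate`` per codon (default 0.25).
``planted-balanced-cluster``
    the neutral model on non-cluster codons, plus one balanced biallelic
    site (two haplotype groups of n/2 sequences each, a single partition
    shared across the cluster) at the third position of every cluster
    codon — the intermediate-frequency configuration that elevates π above
    θ_w, and hence D, inside the cluster.

Mutations are restricted to third codon positions and never create stop
codons, so the ancestral translation remains an aligned reference for every
row.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Literal

import numpy as np

from .errors import InputError
from .seqalign import AlignmentData, ReferenceSeq, translate
from .structures import (
    Atom,
    ONE_TO_THREE,
    Residue,
    ResidueId,
    Structure,
    structure_to_pdb,
)

Geometry = Literal["ideal-helix", "random-coil", "two-cluster"]
MutationModel = Literal["none", "neutral-infinite-sites", "planted-balanced-cluster"]

_BASES = "ACGT"
_SENSE_CODONS = [
    "".join(c) for c in product(_BASES, repeat=3) if "".join(c) not in ("TAA", "TAG", "TGA")
]


@dataclass(frozen=True)
class FixtureSpec:
    """Full description of one synthetic structure + alignment pair."""

    n_residues: int
    geometry: Geometry = "ideal-helix"
    n_sequences: int = 24
    mutation_model: MutationModel = "neutral-infinite-sites"
    cluster_residues: frozenset[int] = field(default_factory=frozenset)
    seed: int = 0
    mutation_rate: float = 0.25  # expected neutral segregating sites per codon

    def __post_init__(self) -> None:
        if self.n_residues < 1:
            raise InputError("n_residues must be >= 1")
        if self.n_sequences < 1:
            raise InputError("n_sequences must be >= 1")
        bad = [p for p in self.cluster_residues if not 1 <= p <= self.n_residues]
        if bad:
            raise InputError(f"cluster_residues outside [1, {self.n_residues}]: {bad}")
        if self.geometry not in ("ideal-helix", "random-coil", "two-cluster"):
            raise InputError(f"unknown geometry {self.geometry!r}")
        if self.mutation_model not in (
            "none", "neutral-infinite-sites", "planted-balanced-cluster"
        ):
            raise InputError(f"unknown mutation_model {self.mutation_model!r}")
        if (
            self.mutation_model == "planted-balanced-cluster"
            and not self.cluster_residues
        ):
            raise InputError("planted-balanced-cluster needs nonempty cluster_residues")


def _rng(spec: FixtureSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, stream])


def _ancestor_codons(spec: FixtureSpec) -> list[str]:
    rng = _rng(spec, 0)
    return [_SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), spec.n_residues)]


# ---------------------------------------------------------------------------
# structures

_SIDE_NAMES = ("CB", "CG", "CD", "CE")


def _make_residue(rid: ResidueId, resname: str, ca: np.ndarray, side_dir: np.ndarray,
                  bfactor: float) -> Residue:
    atoms = [Atom(name="CA", element="C", coord=np.round(ca, 3), bfactor=bfactor)]
    for k, name in enumerate(_SIDE_NAMES, start=1):
        pos = ca + side_dir * (0.8 * k) + np.array([0.0, 0.0, 0.05 * k])
        atoms.append(Atom(name=name, element="C", coord=np.round(pos, 3), bfactor=bfactor))
    return Residue(id=rid, resname=resname, atoms=atoms)


def _ca_positions(spec: FixtureSpec) -> tuple[np.ndarray, np.ndarray]:
    """(n, 3) Cα coordinates and (n, 3) unit side-chain directions."""
    n = spec.n_residues
    rng = _rng(spec, 1)
    if spec.geometry == "ideal-helix":
        theta = np.deg2rad(100.0) * np.arange(n)
        ca = np.column_stack([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * np.arange(n)])
        side = np.column_stack([np.cos(theta), np.sin(theta), np.zeros(n)])
    elif spec.geometry == "random-coil":
        steps = rng.normal(size=(n, 3))
        steps /= np.linalg.norm(steps, axis=1, keepdims=True)
        ca = np.cumsum(3.8 * steps, axis=0)
        side = rng.normal(size=(n, 3))
        side /= np.linalg.norm(side, axis=1, keepdims=True)
    elif spec.geometry == "two-cluster":
        half = n // 2
        centers = np.array([[0.0, 0.0, 0.0], [50.0, 0.0, 0.0]])
        which = np.array([0] * half + [1] * (n - half))
        # rejection-free point-in-ball: radius 5 Å, so blobs stay >= 40 Å apart
        u = rng.random(n) ** (1 / 3)
        direc = rng.normal(size=(n, 3))
        direc /= np.linalg.norm(direc, axis=1, keepdims=True)
        ca = centers[which] + 5.0 * u[:, None] * direc
        side = rng.normal(size=(n, 3))
        side /= np.linalg.norm(side, axis=1, keepdims=True)
    else:
        raise InputError(f"unknown geometry {spec.geometry!r}")
    return ca, side


def make_structure(spec: FixtureSpec, chain: str = "A") -> tuple[Structure, str]:
    """Synthetic structure and its PDB text; translation of the ancestor CDS
    supplies the residue identities, so the structure is alignable to the
    fixture's reference sequence."""
    protein = translate("".join(_ancestor_codons(spec)))
    ca, side = _ca_positions(spec)
    structure = Structure(id=f"fixture-{spec.seed}", chains={chain: []})
    for i in range(spec.n_residues):
        rid = ResidueId(chain=chain, number=i + 1)
        resname = ONE_TO_THREE.get(protein[i], "ALA")
        bfactor = round(5.0 + (i * 7) % 40 + 0.25, 2)
        structure.chains[chain].append(
            _make_residue(rid, resname, ca[i], side[i], bfactor)
        )
    return structure, structure_to_pdb(structure)


# ---------------------------------------------------------------------------
# alignments


def _mutate_third_position(codon: str, rng: np.random.Generator) -> str:
    """A different third base that does not create a stop codon."""
    options = [
        codon[:2] + b
        for b in _BASES
        if b != codon[2] and codon[:2] + b not in ("TAA", "TAG", "TGA")
    ]
    return options[int(rng.integers(0, len(options)))]


def _sfs_count(n: int, rng: np.random.Generator) -> int:
    """Derived allele count drawn from the neutral SFS, P(i) ∝ 1/i."""
    weights = 1.0 / np.arange(1, n)
    return int(rng.choice(np.arange(1, n), p=weights / weights.sum()))


def make_alignment(spec: FixtureSpec) -> tuple[AlignmentData, ReferenceSeq]:
    """Coding-sequence alignment of ``n_sequences`` rows plus the reference
    (the ancestral translation). Gapless and equal-length by construction."""
    codons = _ancestor_codons(spec)
    n_seq, n_res = spec.n_sequences, spec.n_residues
    rows = [list(codons) for _ in range(n_seq)]
    rng = _rng(spec, 2)

    cluster = set(spec.cluster_residues) if spec.mutation_model == "planted-balanced-cluster" else set()
    if spec.mutation_model in ("neutral-infinite-sites", "planted-balanced-cluster"):
        available = [i for i in range(1, n_res + 1) if i not in cluster]
        n_sites = min(int(rng.poisson(spec.mutation_rate * n_res)), len(available))
        if n_seq >= 2 and n_sites > 0:
            sites = rng.choice(available, size=n_sites, replace=False)
            for codon_pos in sorted(int(s) for s in sites):
                derived = _mutate_third_position(codons[codon_pos - 1], rng)
                count = _sfs_count(n_seq, rng)
                carriers = rng.choice(n_seq, size=count, replace=False)
                for row_i in carriers:
                    rows[int(row_i)][codon_pos - 1] = derived
    if cluster:
        half = n_seq // 2
        group_b = set(int(i) for i in rng.permutation(n_seq)[:half])
        for codon_pos in sorted(cluster):
            derived = _mutate_third_position(codons[codon_pos - 1], rng)
            for row_i in group_b:
                rows[row_i][codon_pos - 1] = derived

    aln = AlignmentData(
        names=[f"seq_{i + 1:03d}" for i in range(n_seq)],
        rows=["".join(r) for r in rows],
        alphabet="dna",
    )
    ref = ReferenceSeq(id=f"ref-{spec.seed}", residues=translate("".join(codons)))
    return aln, ref


@dataclass
class Fixture:
    spec: FixtureSpec
    structure: Structure
    pdb_text: str
    alignment: AlignmentData
    reference: ReferenceSeq


def make_fixture(spec: FixtureSpec) -> Fixture:
    """Structure + alignment + reference, all derived from one seed."""
    structure, pdb_text = make_structure(spec)
    alignment, reference = make_alignment(spec)
    return Fixture(spec, structure, pdb_text, alignment, reference)


# ---------------------------------------------------------------------------
# FASTA output (for the CLI and docs)


def alignment_to_fasta(aln: AlignmentData) -> str:
    return "".join(f">{n}\n{r}\n" for n, r in zip(aln.names, aln.rows))


def reference_to_fasta(ref: ReferenceSeq) -> str:
    return f">{ref.id}\n{ref.residues}\n"
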