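# Methods

## The 3D sliding window

For a structure with residues {r₁…r_m} and a radius r (Å), the window at
centre c is W(c) = { r : d(c, r) ≤ r }, a closed ball so that boundary ties
are included deterministically. Windows always contain their centre. Three
residue–residue distances d are available:

| metric     | definition                                   | default |
|------------|----------------------------------------------|---------|
| `min-atom` | minimum over all eligible atom pairs          | yes     |
| `c-alpha`  | CA–CA distance                                |         |
| `centroid` | distance between unweighted atom centroids    |         |

`min-atom` over heavy atoms is the default because it is the most
inclusive reading of a spatial neighborhood for surface-exposed epitopes;
hydrogens are excluded by default since most crystal structures lack them
and their presence would otherwise change neighborhoods between X-ray and
NMR inputs. Hetero residues (ligands, waters) carry no alignment data and
are excluded from windows by default; both filters are flags. Windows span
chains by default (`all-chains`) because conformational epitopes can cross
protomer boundaries in oligomers; `same-chain` restricts them.

Queries run against a scipy cKD-tree but are contractually identical to a
brute-force all-pairs scan; the test suite and the acceptance script verify
exact equality on random structures under all three metrics, plus symmetry
(r ∈ W(c) ⟺ c ∈ W(r)) and radius nesting.

The default radius is 15 Å, a typical maximum extent of an
antibody–antigen interface and therefore a natural window size for immune
selection scans; it is a flag like everything else.

## Sequence ↔ structure ↔ alignment correspondence

The engine needs a map from each structure residue to the alignment
columns carrying its data. It is built in two halves and composed:

1. **Structure → reference.** The one-letter sequence of each selected
   chain (modified residues MSE/SEC/PYL/SEP/TPO/PTR are read as their
   parent letters; anything unknown is X) is globally aligned to the
   reference with BLOSUM62 and affine gaps. The gap parameters follow the
   BLAST convention "open 11, extend 1", i.e. a length-L gap costs 11 + L.
   Mismatched aligned pairs still map — the reference drives the data, the
   structure drives space — while residues aligned to gaps stay unmapped.
   An identity floor (default 30%) guards against aligning the wrong
   protein. Chains are aligned independently, so each protomer of a
   homo-oligomer gets its own map onto the shared reference positions;
   injectivity of the residue→reference map is therefore a per-chain
   invariant. When several chains are selected, a chain that misses the
   identity floor is skipped with a warning (an antibody chain in an
   antigen complex, say); a single selected chain that misses it is an
   error.

2. **Reference → columns.** For nucleotide alignments, the representative
   row (first row by default — rows of one MSA share a frame by
   construction), stripped of gap characters, is translated in all six
   frame/strand combinations with the standard genetic code; each
   translation is aligned to the reference as above and the best-scoring
   combination wins, ties preferring forward strand then lowest frame.
   Each mapped reference position then owns the three alignment columns
   holding its codon's bases in the representative row (gap columns are
   skipped when counting bases). For reverse-sense sequences the triplet
   is stored in ascending column order and read 3'→5'; the detected strand
   is recorded in the output metadata. Protein alignments map one column
   per position by the same representative-row alignment; numeric tables
   are indexed directly by reference position. Codons containing N
   translate to X; stop codons to `*`.

All reference positions and alignment columns are 1-based and inclusive,
in files and in the API, matching FASTA/PDB user expectations.

Intron-containing genomic sequences are out of scope: inputs are assumed
to be aligned coding sequences. Spliced alignment is a project of its own,
and population alignments of antigens are overwhelmingly CDS alignments.

## Window scoring and gap policy

For each centre, the mapped residues of the window contribute their
columns in residue-id order; a window with fewer than `min_data` mapped
residues (default 1) scores null. Under the default **complete-deletion**
policy, every column of the window's sub-alignment containing a gap or an
ambiguity character (N for nucleotide, X for protein) is removed before
scoring; deletion is per-window, not global, to maximise usable columns,
which means different windows can rest on different effective lengths —
the per-residue window sizes are exported for exactly this reason. The
**pairwise** policy keeps all columns and defers to pairwise deletion
inside the statistics (S over columns with ≥2 valid states; each sequence
pair compared over the columns where both are valid). Equivalence with any
particular external tool's gap handling is not claimed.

When a window spans several protomers of a homo-oligomer, each mapped
residue contributes its columns once per residue, so reference positions
shared by two chains appear twice. This inclusive choice is symmetric
across protomers and is recorded in the JSON output metadata
(`duplicate_columns_across_protomers: included`).

## Statistics

All diversity statistics live on the per-alignment (total) scale that
Tajima's D requires — π is the mean pairwise difference count over the
whole sub-alignment — with per-site variants as separate accessors; mixing
the two scales is the classic implementation bug in this area. Columns
count once toward S however many states they show, and multi-allelic
columns contribute per-pair mismatches to π.

Tajima's D uses the standard coefficient chain (a₁, a₂, b₁, b₂, c₁, c₂,
e₁, e₂). D is null — None, never 0, since 0 is a meaningful value of D —
when S = 0, when n < 3, or when the variance estimate e₁S + e₂S(S−1) is
not positive. The last clause matters: c₁ and c₂ vanish identically at
n = 3, so the variance estimate is zero for *every* three-sequence sample
and D is 0/0 there; established implementations fail with a
division-by-zero at n = 3, and this package makes the degeneracy an
explicit null instead. Nulls propagate to the output as empty TSV fields,
JSON `null`, and the `--missing-value` B-factor (default 0).

The test suite checks D against an independently coded straight-line
evaluation on hundreds of random alignments (to 1e−9), against dendropy
on a fixed alignment, and against the sign law sign(D) = sign(π − θ_w).

## Synthetic data generator

The generator emulates the study conditions of a balancing-selection scan
on an antigen at desk scale; a single seed determines every byte of
output (three independent PCG64 streams: ancestor, geometry, mutations).

* **Structures.** An ancestral coding sequence (uniform over the 61 sense
  codons) of 3×n bases is translated to give the residue identities, so
  structure, reference and alignment are mutually alignable. Geometries:
  an idealised helix (Cα rise 1.5 Å, twist 100°, radius 2.3 Å, four dummy
  side-chain atoms per residue pointing radially outward), a 3.8 Å-step
  random coil, and a two-blob layout with centres 50 Å apart (minimum
  inter-blob distance > 40 Å) for unambiguous window-separation tests.
  Coordinates are rounded to PDB precision (3 decimals) so emitted text
  re-parses to an equal model.
* **Neutral model.** Infinite sites on third codon positions: each mutated
  codon carries exactly one biallelic site, the derived allele count i is
  drawn from the neutral site-frequency spectrum P(i) ∝ 1/i, and the
  number of sites is Poisson with mean 0.25 per codon — a realistic
  antigen-scale density giving E[S] = 15 for the 60-residue standard
  fixture. Under this spectrum E[π] = E[θ_w] per site, so whole-alignment
  D is centred near zero; the acceptance script measures the mean over
  500 replicates.
* **Planted balanced cluster.** On top of the neutral background
  (excluded from cluster codons), each cluster codon's third position is
  made biallelic at 50/50 frequency using one shared random partition of
  the sequences into two haplotype groups. Per such site with n = 24,
  π ≈ 1.04 versus θ_w ≈ 0.27, so windows covering the cluster show
  strongly positive D. Mutations avoid creating stop codons.

What the generator does **not** emulate: linkage/recombination structure
from a genuine coalescent (sites are independent given the SFS), realistic
side-chain chemistry and packing, alignment errors, sequencing gaps and
ambiguity codes, and insertions/deletions. Passing tests therefore
demonstrate correctness of the machinery — mapping, windowing, statistics,
I/O — under idealised data, not robustness to the full messiness of field
samples; the gap-policy code paths are exercised by dedicated unit tests
with hand-built gapped alignments instead.

## Structure I/O

Parsing goes through gemmi for both PDB and mmCIF (`auto` detects by
extension then content). Only the first model of multi-model NMR files is
used (logged). Alternate conformations are resolved at parse time — per
atom name the highest-occupancy conformer wins, ties keeping the first in
file order — so the model downstream is single-conformer. Hetero
classification follows the file's HETATM flag, except that the common
modified polymer residues above stay polymer; waters are always hetero.
Residues are addressed by author numbering plus insertion code, never by
serial position, so output cross-references the deposited structure.

Output is PDB v3.3 fixed columns written by the package's own minimal
serializer, which makes the output contract checkable byte-for-byte: an
annotated file differs from a plain re-serialization of the parsed model
only in the B-factor columns (61–66, `%6.2f`). Scores outside the
representable range (−100 < v < 1000) raise a formatting error suggesting
a rescale rather than corrupting columns. mmCIF output, multi-model
ensembles and connectivity records are non-goals.

## Problem sizes and determinism

The default verification scale — ~50 random structures up to 300 residues
for the spatial oracle, 120 random alignments for the D oracle, 20
planted-cluster replicates of 60 residues × 24 sequences, 500 neutral
replicates — keeps the full suite and the acceptance script each within a
few seconds on one core while giving the stochastic checks comfortable
margins. Every randomised component is seeded (hypothesis profiles are
derandomised); two runs with identical inputs produce byte-identical TSV,
JSON and PDB outputs, and the JSON embeds the full effective
configuration.

## Known limitations

* No significance testing for D (no beta-approximation p-values, no
  per-window permutation tests); scores are descriptive.
* Windows weight all residues equally — no solvent-accessibility or
  surface filtering.
* The aligner is a plain global Needleman–Wunsch; heavily engineered
  constructs (large tags, circular permutants) may need pre-trimming.
* Crystal-symmetry neighbours are invisible: only chains present in the
  file define space.
* Per-window complete deletion means neighbouring windows can rest on
  different column sets when the alignment is gappy; compare window sizes
  and use the pairwise policy as a cross-check.
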