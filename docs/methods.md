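# Methods

## Scope and data model

`strucmap` re-implements, as a library plus CLI, the curation pipeline
behind a structure-guided variant browser: structure ingest and
decomposition, chain-to-reference renumbering with discrepancy detection,
structure filtering and relevance ranking, residue micro-environment
analysis, ortholog-conservation profiling, and variant-to-structure
mapping. It deliberately excludes everything a hosted service would add:
no fetching from PDB/UniProt, no biological-assembly reconstruction from
symmetry operators (assemblies are accepted as the files supplied), no MSA
construction (alignments are consumed pre-made), no visualization, and no
clinical interpretation of variants. One reference sequence per gene;
isoform arbitration is out of scope.

## Structure ingest

Coordinates are parsed with gemmi in both PDB and mmCIF dialects. Only the
first model of multi-model (NMR) files is used. Alternate locations are
resolved per atom name to the highest-occupancy conformer; ties go to the
first altloc label alphabetically. Residues whose names are standard amino
acids (or common nonstandard ones — MSE, SEP, TPO, PTR, … — mapped to
their parent) form chains; everything else becomes a ligand entry. Water
is recognized intrinsically; other ligand categories (approved drug,
investigational, sugar, ion, buffer) come from a user-supplied TSV
dictionary, defaulting to `other` for unknown codes. Water and buffer
entries are hidden by default, mirroring how a curated browser hides
irrelevant molecules. Chains of ≤ 30 residues with no reference mapping
are classified as peptides; the threshold is a parameter because the
sources we emulate count peptides without stating a length rule.

Header metadata (experimental method, resolution, R-work/R-free, declared
sequence differences, declared unobserved residues) is read by targeted
extractors: fixed-column EXPDTA / REMARK 2 / REMARK 3 / SEQADV /
REMARK 465 records for PDB, and the `_exptl`, `_refine`,
`_struct_ref_seq_dif` and `_pdbx_unobs_or_zero_occ_residues` categories
for mmCIF. gemmi's own metadata objects are not used here because they do
not uniformly surface these records from minimal files, and the fixture
writer emits exactly these canonical records.

## Chain-to-reference alignment and renumbering

Each candidate chain is aligned to the reference with Biopython's
`PairwiseAligner`: global dynamic programming with BLOSUM62, affine gaps
(open 11, extend 1), and free end gaps on the reference side only — a
semi-global alignment in which reference overhangs cost nothing but every
chain residue must be placed. Identity is computed over aligned non-gap
columns; mappings with identity below a configurable floor (default 0.30)
are rejected as unconfident. On identical or near-identical sequences the
optimal alignment is unique, so the substitution matrix choice is
immaterial there; the floor guards the divergent cases. A pipeline-level
`target_chain_ids` annotation can restrict mapping to curator-designated
chains, which is how real chain↔accession assignments work; without it,
any chain clearing the floor is mapped and the rest (partners, peptides)
are left unmapped.

Renumbering assigns each resolved residue its 1-based reference position.
Discrepancies are read off the alignment: mismatch columns are mutations,
reference positions inside the aligned span with no residue are missing,
and chain residues aligned to no reference position are insertions,
labelled `p+k` after their anchor position `p` (insertion-coded residues
carry no reference number; the sources are silent on a convention, so the
ordinal tag is ours). Every discrepancy is flagged declared/undeclared by
comparison with the header: mutations and insertions against the declared
sequence differences by (chain, author number), missing residues against
the declared-unobserved list using the author number they would have
carried, inferred from the offset of the nearest aligned anchor (exact for
uniform-offset chains; approximate only if the offset changes inside an
unresolved region).

Filter semantics are read literally from their wording: a chain is kept
iff its missing fraction over the spanned region is strictly below 0.30
("fewer than 30%"), and a structure is dropped iff its mapped chains carry
strictly more than 10 mutations ("more than ten"), unless its entry id is
on an explicit override list — the escape hatch for a gene whose only
available structure is heavily engineered. A structure with no kept chain
is dropped regardless of overrides.

## Relevance scoring

The original scoring rules live in unpublished supplementary material, so
this module specifies a transparent additive scheme over the same declared
criteria, with every weight configurable and the defaults documented:
coverage (fraction of the reference resolved by the best kept chain)
× 40; a resolution bonus linear from 0 points at 4.0 Å to 20 points at
1.0 Å, clamped, and 0 when no resolution applies (solution NMR); method
priors x-ray/neutron 10, cryo-EM 8, NMR 6, fiber 4, model 2; +15 for a
bound approved drug, +8 for an investigational one, +8 for a partner
chain; −3 per mutation. The high/low tier cutoff defaults to 50. The
scheme is monotone in each criterion by construction and exactly additive,
which makes it auditable: the exemplar metadata (full coverage, 1.0 Å
x-ray, drug, partner, no mutations) sums to 40+20+10+15+8 = 93. Ranking
is by descending score with deterministic tie-breaks (better resolution,
then lexicographic entry id). Active/inactive state and domain tags come
from a curator-supplied remark TSV; no automatic state or domain
assignment is attempted.

## Interaction typing

Contacts around a query residue/ligand are typed on heavy atoms only —
no hydrogen placement, no energies:

- **hydrogen bond**: donor/acceptor heavy-atom pairs from per-residue
  chemistry tables, distance ≤ 3.5 Å, with the antecedent–donor–acceptor
  angle ≥ 90° as a directionality proxy (accepted on distance alone if the
  antecedent atom is absent);
- **ionic**: cationic atoms (Lys NZ; Arg NH1/NH2/NE; His ring N;
  free N-terminus) to anionic atoms (Asp/Glu carboxylate O; free
  C-terminus OXT; phosphate O) ≤ 4.0 Å — His is evaluated as both
  aromatic and potentially cationic, protonation never inferred;
- **hydrophobic**: apolar-carbon pairs ≤ 4.5 Å (per-residue tables;
  all ligand carbons count as apolar, a documented simplification);
- **π-stacking**: aromatic ring centroids (Phe, Tyr, His, both Trp rings)
  ≤ 5.5 Å; detection is by centroid distance only, with the plane tilt
  recorded and used to label the geometry parallel (≤ 30°) or tilted —
  the tilt is annotation, not a rejection criterion;
- **cation–π**: cationic atom to ring centroid ≤ 6.0 Å.

All cutoffs live in `GeometryConfig` and are package choices from common
structural-biology practice — the display conventions being emulated
publish none — so they are configurable and version-pinned with the
package. Neighbour search uses a k-d tree prefilter but is contractually
identical to a brute-force all-pairs scan; the test suite enforces exact
equality against an independent plain-Python oracle on random scenes.
Other chains are included only on request (the multi-chain display
behaviour), with inter-chain contacts flagged.

## Conservation

The MSA (aligned FASTA or Clustal) must contain the human reference,
identified by accession or an `organism=human` header tag; its ungapped
row defines the column↔position maps. Conservation per reference position
is identity to the human residue over non-gap ortholog rows, with the
human row excluded from numerator and denominator. Positions with no
non-gap ortholog are explicitly *undefined* (`None`, written `NA`) —
never 0 or 1, because both would be readable as evidence. Identity was
chosen over entropy or similarity-class scores because it is what the
emulated alignment panel communicates (conserved vs not); richer scores
are extension points. Reviewed sequences carry an asterisk on their
organism label, following the convention of the source material.

## Variant grammar and presence

Variant strings follow HGVS-protein short forms without the `p.` prefix
(accepted and stripped); three-letter codes normalize to one-letter. Six
types are parsed: missense, nonsense, deletion, insertion, duplication,
frameshift. Canonical re-serialization round-trips for all types in both
notations. Effect annotations are curated externally and passed through
verbatim; only position logic is computed. Frameshift and nonsense
variants map to their start position only — downstream truncation is
annotation, not geometry; insertions touch their two flanking positions.
Presence on a renumbered chain partitions the variant's positions into
present/absent resolved sets (full / partial / absent status); a missense
whose stated reference residue disagrees with the reference sequence
yields a warning, not an error. The partial/absent distinction is a
superset of the shown/shaded dichotomy a display would use.

## Synthetic fixtures

The fixture generator is first-class, tested code. Everything is a pure
function of a seeded spec: reference sequences are uniform over the 20
amino acids; chains are ideal α-helices (rise 1.5 Å, 100° turn, 2.3 Å
radius, giving Cα–Cα ≈ 3.8 Å) with N/CA/C/O and a pseudo side-chain CB —
sufficient because no consumer computes chemistry from helix fixtures
beyond distances. Contact scenes instead place chemically typed residue
fragments (Lys, Glu, Arg, Ser, Leu, Asn, Phe, His with real atom names
and planar rings) at random rotations/translations in a box, ~100 heavy
atoms across two chains. Structure fixtures apply a recorded set of
author-number offsets (0–100), substitutions (0–8), deleted ranges (0–3)
and insertion runs (0–2), declaring a configurable fraction in the header
so undeclared-modification detection is exercised.

Three generator constraints make injected-edit recovery exact rather than
ambiguous, which is what the recovery checks assert: edits are separated
by a minimum buffer and kept off the chain termini; deletion ranges are
placed only where the flanking residues differ from the gap edges, so the
optimal gap placement cannot slide; inserted residues are drawn from
letters absent in the flanking reference window. These are properties of
the generator's design (an ambiguous optimum has no unique ground truth to
recover), not tuning. MSA fixtures hit per-member identity targets exactly
by construction (mutating `round((1−t)·n)` of the non-gap positions),
emulating a nine-ortholog vertebrate panel from near-identical primates to
distant fish/amphibian.

What the fixtures do **not** emulate: real side-chain rotamers, crystal
contacts, B-factor structure, sequence composition bias, alternate
conformations beyond the synthetic altloc cases, and genuinely ambiguous
alignments (tandem repeats, low-complexity regions). Passing tests
therefore demonstrate the correctness of the bookkeeping and geometry on
well-posed inputs, not robustness to pathological real-world entries —
for those, the identity floor and the explicit reject/reason reporting are
the safety net.

## Determinism and numerics

Every stage is deterministic: alignment is exact DP, contact lists are
sorted by (kind, distance, partner), ranking ties break on resolution then
entry id, and pipeline outputs are byte-identical across reruns of the
same config, each output stamped with a 12-hex-digit SHA-256 config hash.
Angles are computed with clamped arccos; ring planes by SVD of centered
ring coordinates (the oracle in the tests uses cross products instead,
keeping the two derivations independent). Degenerate inputs have defined
behaviour: empty structure files and ragged alignments raise typed errors;
an empty structure directory yields an empty ranked table with a warning
(a gene may simply have no experimental structure); a query residue
lacking the chemistry for a requested interaction kind yields an empty
list, not an error.

## Problem sizes in the verification suite

The randomized checks use 50 structure fixtures (reference length 200) for
edit recovery, 20 random contact scenes (~100 heavy atoms, every residue
as query) for oracle equivalence, and the three-structure demo workspace
for the end-to-end run; the full suite plus the acceptance script completes
in a few seconds on one CPU. Sizes were chosen to exercise every code path
and edit-type combination repeatedly while keeping the suite instant to
run.
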