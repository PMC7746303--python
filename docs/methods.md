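# Methods

This note records the model behind the package, the conventions and
parameters that matter, and the design decisions taken where more than one
reasonable choice existed. It states nothing that the test suite or
`scripts/acceptance.py` does not itself compute.

## Residue representation

Each polymer residue is reduced to a backbone and a sidechain
representative point. For amino acids these are Cα and Cβ; for nucleotides
C4′ and C1′. The reduction deliberately ignores sidechain identity beyond
the type token so that chemically different residues (and position-specific
exchanges between them) remain comparable.

Glycine has no Cβ; a virtual one is produced by least-squares superposition
of an ideal L-alanine fragment (N, Cα, C — ideal-geometry coordinates from
the chemical component dictionary, frozen as constants) onto the residue's
backbone, transplanting the alanine Cβ. The construction is equivariant
under rigid motion and places the virtual Cβ 1.53 Å from Cα. Residues
missing the required representative atoms (e.g. Cα-only models) cannot be
represented and are excluded at load time, counted in the load report.

Cleaning at load time: hydrogens removed, first alternate location kept,
waters/ions/ligands dropped, and modified components translated to parent
tokens through a configurable table (selenomethionine → M, phosphoserine →
S, ...). Components that are neither standard nor mapped are excluded and
reported rather than guessed. Amino-acid tokens are upper-case one-letter
codes; nucleotides use lower-case a/c/g/t/u so adenosine never collides
with alanine.

Biological assemblies are expanded by applying the file's assembly
operators; every residue address carries its operator id ("1" is the
identity / asymmetric unit), so motifs spanning assembly copies are
first-class. When an entry defines several assemblies, the caller chooses
one (the CLI default indexes the asymmetric unit; pass `--assembly 1` to
index the first assembly); which assembly to index is a corpus-level
policy, not a property of the method.

## Pair descriptor and binning

A residue pair within the 20 Å backbone-distance cutoff is measured by
(d_b, d_s, θ): the distance between backbone representatives, the distance
between sidechain representatives, and the angle between the two
backbone→sidechain vectors. All three are invariant under rigid motion and
symmetric under swapping the residues.

Binning is floor-based with left-closed/right-open intervals: 1 Å bins for
distances (d_b bins 0–19), 20° bins for the angle (bins 0–8, with θ = 180°
clamped into bin 8). The type pair is sorted lexicographically ("AC", never
"CA"). The worked example fixes the convention: a His/Ser pair at
(8.4 Å, 7.2 Å, 105°) renders as `HS-8-7-5`. d_s is capped at 32 Å for
integer packing; since d_s can exceed d_b by at most about twice the
representative-vector length (~3 Å), no pair under the 20 Å cutoff ever
reaches the cap in practice. Keys pack bijectively into one integer,
monotone in (type pair, d_b bin, d_s bin, θ bin) lexicographic order.

Because binning is a hard partition, lookups consult neighboring bins: at
tolerance t, the full Cartesian product of the three measures' neighborhoods
((2t+1)³ bins in the interior, clamped at range edges). Tolerance 1 — three
bins per measure — is the default; any two geometries that agree to within
one bin on every measure are mutually visible, so no match is lost to a
single bin border.

Each stored occurrence carries one extra bit beyond the ordered locator
pair: whether the first (locator-smaller) residue carries the first or the
second token of the sorted type pair. Without it, a retrieved "DH" pair
could not be oriented onto (Asp-role, His-role) without loading
coordinates; with it, candidate assembly stays purely index-based.

## Index layout

One file per descriptor bin (named by the packed key, two-level fan-out on
the key modulo 256), containing postings as interned chain/operator token
tables plus flat little-endian integer arrays; a JSON manifest records
indexed ids, total pair count, bin count and a checksum over the bin file
listing. MessagePack is the natural off-the-shelf framing for this design;
the environment pins a dependency set without it, so the package uses an
equivalent minimal struct-based framing of its own (same layout, same
interning). Builds write into a temporary sibling directory and publish by
a single rename; incremental updates rewrite only the touched bins and are
required — and tested — to be bin-for-bin identical to a fresh build over
the union corpus.

The coordinate store keeps one file per structure with a per-residue offset
table so scoring reads exactly the candidate residues, never the siblings
(important for ribosome-scale entries). Stored coordinates are rounded to
0.1 Å; this bounds the RMSD of a self-match at roughly 0.03–0.12 Å and is
the floor visible in all end-to-end scores.

## Query pipeline

A query is an ordered set of roles (reference residue + allowed tokens,
exchanges included) with all admissible pair geometries (d_b < 20 Å)
computed from the reference coordinates. If the admissible-pair graph is
disconnected the motif cannot be expressed in indexable pairs and is
rejected as too extended.

Motifs of 2 or 3 residues use all admissible pairs. Larger motifs are
pruned to a minimum spanning tree (Kruskal over a simple union-find; edge
weight = reference d_b, ties broken lexicographically by role pair, making
pruning deterministic). d_b weighting needs no index statistics at query
time; rarity-weighted edges would be a possible refinement. Constraints
dropped by pruning are not re-checked geometrically before retrieval — a
candidate distorted in an omitted pair simply scores a high RMSD and is
removed by the cutoff. The safety direction (pruning only relaxes
constraints, so no hit of the full edge set is lost) is tested.

Per edge, one descriptor key is generated per combination of the two
roles' allowed tokens and expanded by the tolerance; duplicate keys are
deduplicated and bin reads are cached across edges. Structures missing
postings for any edge are rejected before any per-structure work.
Surviving structures are searched by depth-first backtracking over the
edges (ordered so each edge extends an already-anchored role), enforcing
injectivity and the per-edge occurrence tables; the result is the exact
set of assignments in which every retained edge is witnessed by a
retrieved occurrence with compatible tokens. An exhaustive, index-free
reference implementation (`strucmotif.exhaustive`) recomputes this set
from raw structures and serves as the independent oracle in the test
suite and acceptance script.

## Scoring

Atom correspondence is by plain name intersection per role — exchanges
simply pair the shared names — with three selectable sets: `all`
(every shared heavy atom), `sidechain` (shared non-backbone atoms; for
nucleotides the sugar-phosphate moiety counts as backbone and C1′ as
sidechain), and `representatives` (the two representative points only).
`sidechain` is the reporting default: all-atom superpositions can
overweight backbone atoms when chain directions differ, and the sidechains
carry the function. No attempt is made to resolve chemically ambiguous
atom labels (e.g. the two ring branches of tyrosine). Every result file
records the mode used.

Superposition uses the quaternion formulation: the optimal proper rotation
is the top eigenvector of the 4×4 quaternion key matrix built from the
cross-covariance of the centered coordinate sets (reflections are
impossible by construction). The RMSD is evaluated from the realized
superposition rather than from the eigenvalue, which loses about half the
significant digits when the optimum is near zero; agreement with an
SVD-based solution is verified to 1e-6 Å and exact-superposable cases
return 0 to 1e-9 Å. Transforms are reported mapping hit onto query so hits
can be overlaid on the reference. Hits sort by (RMSD, structure id,
assignment), making runs byte-reproducible.

No statistical significance is attached to a hit; RMSD ranking plus expert
inspection is the intended use, and a 1 Å cutoff is a practical working
threshold for "biologically meaningful" in the examples and tests.

## Synthetic data

The generator emulates exactly the features the descriptors see: chains as
self-avoiding random walks with 3.8 Å backbone steps (the Cα–Cα virtual
bond length of trans peptides), sidechain representatives 1.5 Å from the
backbone point in random directions, uniform amino-acid composition, and a
minimal consistent atom record (N, Cα, C, O, Cβ; glycine omits Cβ so the
loader's reconstruction path is exercised). Corpora are emitted as real
mmCIF so every test crosses the parser. It does not model Ramachandran
statistics, secondary structure, sterics beyond self-avoidance, sequence
composition bias, or realistic sidechain geometry — so passing tests
demonstrate correctness of indexing, retrieval, assembly and scoring, not
biological sensitivity on real structures.

Planting substitutes a rigidly transformed motif copy (uniform random
rotation, translation within ±50 Å) at chosen chain positions, then adds
independent Gaussian noise of standard deviation σ to every coordinate; σ
is in Å and the truth table records every planted assignment. Recall is
measured against the truth at a 1 Å RMSD cutoff.

The reference motif is a synthetic stand-in for a serine-protease
catalytic triad: three residues (His, Asp, Ser) constructed by
least-squares so that each pair hits a prescribed (d_b, d_s, θ). The
His/Ser pair is built exactly to the published worked-example geometry
(8.4 Å, 7.2 Å, 105° → `HS-8-7-5`), which calibrates the binning
convention; the other two pairs use plausible triad-scale values placed
mid-bin, because a fixture sitting exactly on a bin border would make
noise-robustness measurements knife-edge by construction rather than
informative.

## Verification problem sizes

The acceptance script and tests run at desk scale: oracle-equivalence over
20 randomized corpora of 10–30 structures with 30–100 residues each at
tolerances 0/1/2; recall over 12-structure corpora with 8 planted
instances at σ ∈ {0, 0.1, 0.3} Å; 100 random pairings for the
superposition cross-check; ~11-structure corpora for the index-algebra
checks. Archive-scale census numbers (bin counts, occurrence totals over
hundreds of thousands of entries) depend on the archive snapshot and are
out of scope.

## Known limitations

- Hit significance is unquantified (open problem); RMSD is the only score.
- Ambiguously labelled atoms are paired by name only, which can inflate
  RMSD for symmetric sidechains.
- Unmapped modified components are excluded rather than approximated.
- One assembly (or the asymmetric unit) is indexed per entry; indexing
  several assemblies of the same entry requires distinct structure ids.
- The coordinate store's 0.1 Å rounding puts a ~0.03–0.12 Å floor under
  reported RMSDs; sub-0.1 Å distinctions between hits are not meaningful.
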