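# Methods

## Design model

The toolkit models CRISPRi silencing by *S. pyogenes* dCas9 inside
bacterial ORFs. Binding requires a 5′-NGG-3′ PAM immediately 3′ of a
20-nt protospacer; silencing by elongation block is effective when the
sgRNA base-pairs with the non-template (sense) strand of the gene.
Specificity is dominated by the PAM-proximal seed, so genome-wide
uniqueness is assessed by exact matching of seed + PAM rather than
full-length alignment. The model is purely sequence-based: no
thermodynamics, no chromatin or expression context, no mismatch-weighted
off-target scores.

### Strand mechanics

"Target the non-template strand" fixes where the protospacer lives: the
sgRNA is complementary to the sense strand, so protospacer + PAM sit on
the template strand. In sense-strand coordinates the PAM therefore
appears as `CCN` with the reversed protospacer 3′ of it, and enumeration
scans the sense sequence for `CCN` at offset *i* with
*i* + 23 ≤ feature length, emitting

    spacer = revcomp(sense[i+3 : i+23]),  pam = revcomp(sense[i : i+3])

`dist5 = i` measures from the feature's 5′ end to the start of the
protospacer+PAM footprint in feature orientation. Any fixed monotone
convention gives the same 5′-proximity ranking; this one makes the
planted-fixture arithmetic exact. A `strand_rule` parameter
(`non_template` | `template` | `both`) lets users with the opposite
convention override; template-strand candidates are flagged.

Both protospacer and PAM must lie entirely inside the annotated feature
(design is "within the coding sequence"), so the minimum targetable
feature length is spacer + PAM = 23 nt. This is consistent with short
sRNAs (e.g. a 66-nt sRNA) being targetable while 20-nt features are not.

### Parameters (`DesignParams`)

| parameter | default | meaning |
|---|---|---|
| `spacer_len` | 20 nt | base-pairing region of the sgRNA |
| `seed_len` | 12 nt | PAM-proximal seed used for uniqueness |
| `exact_core_len` | 7 nt | PAM-adjacent region requiring perfect complementarity |
| `min_pairing_run` | 12 nt | contiguous matched run (from PAM) required for silencing |
| `pam` | `NGG` | PAM motif, position 1 a wildcard |
| `gc_warn_below` | 0.40 | seed GC fraction below which a warning flag is set |
| `require_unique` | true | discard guides with >1 genome-wide binding site |
| `strand_rule` | `non_template` | which strand the sgRNA pairs with |

Invariant: `exact_core_len ≤ min_pairing_run ≤ seed_len ≤ spacer_len`.
Because the pairing run is contiguous and anchored at the PAM, requiring
run ≥ 12 subsumes the 7-nt perfect-core rule; `validate_pairing` reports
the run length and 1-based mismatch positions counted from the PAM.
Under defaults a single mismatch at positions 1–12 abolishes pairing and
at positions 13–20 does not — the test suite sweeps all 20 positions.

The uniqueness pattern is `seed + N + GG` (14 informative nt). The PAM's
first base is the wildcard; requiring the GG at PAM positions 2–3 is the
NGG reading of the motif. Whether a seed match *without* any PAM should
count as a binding site is a judgment call; the default requires the
PAM, since PAM-less sites are not bound productively by dCas9. Matching
is exact over unambiguous bases: an `N` in the genome never matches any
pattern position. Origin-spanning matches are counted only for records
flagged circular; annotated features may not wrap the origin.

The GC warning threshold (0.40) sits strictly between an observed weak
seed (≈33 % GC, clearly reduced silencing) and the effective 42–58 %
band. It is a warning, not a filter: weak-seed guides still silence,
just less.

Ranking is ascending `dist5` with a deterministic tie-break
(record, coordinate, lexicographic spacer) so outputs are reproducible
byte for byte.

## Escape alleles

Complementing a polar knockdown needs a plasmid copy of the target that
the resident guide cannot silence. `design_escape_alleles` enumerates
every combination of synonymous single-codon substitutions at the codons
overlapping the seed (and the PAM, whose GG can sometimes be destroyed
synonymously), keeps alleles with ≥ `min_codon_changes` changed codons
*or* a disrupted PAM, and verifies each one protein-identical by
translation (bacterial table 11; start and stop codons are never
touched). Two changed seed codons are the default recommendation; a
documented single-change mode exists because one proline-codon change in
the 7-nt core has been shown to fully relieve silencing, whereas a
single change further from the PAM may only partially relieve it. That
observation motivates the coarse `predicted_strength` label ("full" when
≥ 2 seed codons change, the PAM is lost, or ≥ 1 nt changes in the 7-nt
core; otherwise "partial") — it is a heuristic, not a fitted model.
Codon-usage optimization and mRNA-structure effects are out of scope;
rare-codon alleles are not filtered.

`verify_escape` closes the loop: it re-extracts the protospacer instance
from the mutant CDS and re-runs the pairing rule and PAM check. Escape
succeeds iff pairing fails or the PAM's GG is destroyed. Every allele
the designer emits passes this check (a tested closure property).

## Operon scope and census

`knockdown_scope` partitions an operon at the target: members with
`operon_index` ≥ target are silenced (polar elongation block), smaller
indices are unaffected. Operon structure must be provided in the
annotation (`operon_id`/`operon_index` GFF3 attributes); the toolkit
does not infer operons from intergenic distances.

`targetability_census` asks per feature whether ≥ 1 candidate exists.
By default it does **not** apply the uniqueness filter — PAM
availability is the limiting factor the census is about — but
`apply_uniqueness=True` is available and can only reduce counts
(a tested monotonicity property).

## Synthetic fixtures

`crispritools.fixtures` generates genomes in which the truth is exact by
construction, not with high probability: background sequence is i.i.d.
at a target GC fraction (0.38 by default, a lactococcal-like AT-rich
composition); CDS features get a start codon, random sense codons and a
stop; requested `CCN` sites are planted at given sense offsets; extra
copies of a candidate's seed+PAM instance are planted in background as
off-target decoys; and a bounded repair loop (cap 1,000 iterations)
removes every unintended in-feature PAM site and every accidental
genome-wide match of a tracked specificity pattern, erroring out rather
than emitting an inexact truth table. Planted footprints are protected
from repair so the recorded spacers are final. A single seeded
`numpy` generator drives everything; identical spec + seed gives
byte-identical FASTA/GFF3/JSON output.

What the fixtures do *not* emulate: real codon bias, oligonucleotide
composition, repeat families, or realistic gene density. Passing the
planted-truth suites therefore demonstrates the correctness of the
scanning/counting/recoding logic, not performance characteristics on any
particular real genome — on real data, guide availability and off-target
rates are properties of the input genome, and annotation quality
(operon structure especially) is the user's responsibility.

## Coordinates, I/O and numerical choices

Internal coordinates are 0-based half-open; GFF3 I/O is 1-based
inclusive; BED6 output is 0-based half-open. FASTA input is uppercased,
`U`→`T`, and non-ACGTN IUPAC ambiguity codes collapse to `N` with a
warning (candidate enumeration and matching are defined only over
unambiguous bases; spacers or PAMs containing `N` are dropped). CDS
features whose length is not a multiple of 3 are flagged, not rejected;
they are excluded from escape design. Translation uses NCBI table 11
with the initiator translated per table (no forced methionine) —
escape design never touches the start codon, so initiator handling
cannot affect alleles.

All CLI commands are deterministic given inputs and configuration; logs
record parameters and input checksums. Exit codes distinguish success
(0), empty result (3), invalid input (2) and I/O failure (4).

## Problem sizes in the test and acceptance runs

The oracle-equivalence suites compare production scanning against naive
position-by-position brute force on 100 random 2-kb single-replicon
genomes (mixed strands, some circular) — large enough to exercise every
code path including origin wrap, small enough that the deliberately slow
oracle stays instant. The acceptance script uses a 4-kb planted fixture
with two genes, ten sRNAs (six targetable) and a triplicated off-target
pattern. These sizes are the package's own test-design choice; the
scanning code itself is linear in genome length and handles
multi-megabase bacterial genomes without special treatment.

## Known limitations

* No on-target efficiency model beyond the seed-GC flag, and no
  mismatch-weighted off-target scoring; the uniqueness screen is exact
  seed+PAM matching, mirroring the discard-if-multi-site design rule.
* Promoter/intergenic targeting rules are not implemented (design is
  within annotated features only).
* The sgRNA scaffold is treated as an opaque user-supplied string; no
  default scaffold or vector flanks ship with the package.
* Operon structure is trusted as annotated; mixed-strand operons are
  rejected rather than repaired.
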