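# crispritools

CRISPRi sgRNA design toolkit for bacterial genomes.

CRISPR interference silences a gene by parking a catalytically dead Cas9
(dCas9), guided by a single-guide RNA (sgRNA), on the DNA as a roadblock
for RNA polymerase. Designing guides that silence strongly and
specifically inside an ORF follows a small set of well-established rules,
and this package implements that design computation end to end for
annotated bacterial genomes such as *Lactococcus lactis*:

* **Candidate enumeration** — the sgRNA must base-pair with the
  **non-template** (sense) strand, so the 20-nt protospacer and its
  5′-NGG-3′ PAM lie on the template strand; operationally each gene's
  sense sequence is scanned for `CCN` and the 20 nt downstream are
  reverse-complemented into the spacer. Both protospacer and PAM must lie
  inside the annotated feature.
* **Uniqueness screening** — off-target binding is dominated by the
  PAM-proximal **seed**; guides are screened by exact matching of a
  14-nt-informative specificity pattern (12-nt seed + the GG of the PAM,
  the N position a wildcard) against both strands of every replicon, and
  guides with more than one binding site are discarded.
* **Ranking** — surviving guides are ordered by proximity to the 5′ end
  of the coding sequence (strongest knockdown), with a warning flag on
  seeds below 40 % GC (≈33 % GC seeds silence noticeably more weakly than
  the effective 42–58 % band).
* **Pairing validation** — a site is considered silenced while the
  contiguous matched run from the PAM-proximal end is ≥ 12 bp, which
  subsumes perfect complementarity over the 7 PAM-adjacent nucleotides.
* **Operon scope** — the roadblock is polar: the target and all
  downstream co-operonic genes are silenced, upstream genes are not.
* **Escape alleles** — for complementation, the target CDS is recoded
  with synonymous codon substitutions in the seed (or the PAM is
  destroyed synonymously) so the resident guide can no longer silence
  the plasmid copy; two changed seed codons are the recommended default.
* **sRNA census** — short regulatory RNAs are often PAM-poor; the census
  reports which features admit at least one guide (minimum feature
  length: 20 + 3 = 23 nt).
* **Cloning oligos** — guide swapping by quick-fusion cloning uses two
  complementary 50-nt primers per guide, built 15 nt vector overlap +
  20-nt spacer + 15 nt vector overlap.

A deterministic synthetic-fixture generator (`crispritools.fixtures`)
plants PAM sites, off-target decoys, operons and sRNAs into random
genomes with an exact machine-readable truth table, so the entire
workflow is testable without downloading any reference genome.

## Worked example

Generate a small synthetic genome and design guides:

```
$ crispri fixture --seed 9 --out fx
$ crispri design --genome fx/genome.fasta --gff fx/features.gff3 --out guides
WARNING crispritools: gene_00 rank 2: seed GC 25% below 40% — weaker silencing likely
3 guides kept, 0 discarded across 3 feature(s) -> guides

$ cat guides/guides.tsv
feature_id  spacer                pam  record  proto_start  proto_end  pam_strand  dist5  seed          seed_gc  offtarget_count  low_gc_flag  rank
gene_00     GTCGTTCTAGTCAGAGAACC  CGG  rec_0   72           92         -           9      AGTCAGAGAACC  0.5      1                False        1
gene_00     AATGTTAAACACGATAAATT  TGG  rec_0   123          143        -           60     ACACGATAAATT  0.25     1                True         2
srna_00     TAGATTTTTACCATTATATT  AGG  rec_0   444          464        -           34     TACCATTATATT  0.1667   1                True         1
```

Reading the first row: `gene_00`'s best guide sits 9 nt from the start
codon (`dist5`, rank 1 because closest to the 5′ end), its protospacer
occupies 0-based interval [72, 92) on the template (−) strand with a CGG
PAM, it has exactly one genome-wide binding site (`offtarget_count`), and
its 50 % GC seed needs no warning. The second guide is unique too but its
25 % GC seed predicts weaker silencing (`low_gc_flag`).

Census over the annotated sRNAs (one of the two is only 20 nt, shorter
than the 23-nt protospacer+PAM footprint, hence untargetable):

```
$ crispri census --genome fx/genome.fasta --gff fx/features.gff3 --out cen
{"n_targetable": 1, "n_total": 2}
```

Cloning oligos for the top guide (overlaps are your linearized vector's
flanks):

```
$ crispri oligos --genome fx/genome.fasta --gff fx/features.gff3 \
    --targets gene_00 --up15 TACGAATTCGAGCTC --down15 GTTTTAGAGCTAGAA --out oli
$ cat oli/oligos.tsv
name        sequence                                            length
gene_00_FW  TACGAATTCGAGCTCGTCGTTCTAGTCAGAGAACCGTTTTAGAGCTAGAA  50
gene_00_RV  TTCTAGCTCTAAAACGGTTCTCTGACTAGAACGACGAGCTCGAATTCGTA  50
```

Both primers are 50 nt (15 + 20 + 15) and mutually reverse-complementary;
annealed, they fuse the new spacer into the linearized sgRNA vector.

Escape alleles for complementing a polar knockdown:

```
$ crispri escape --genome fx/genome.fasta --gff fx/features.gff3 \
    --target gene_00 --out esc
```

writes a table of synonymous recodings (changed codons, nt changes in
seed and 7-nt core, PAM status, predicted strength) plus the mutant CDS
as FASTA; every emitted allele is verified protein-identical and
pairing-breaking.

The same functionality is available as a library
(`crispritools.design_guides`, `targetability_census`,
`design_escape_alleles`, `make_guide_swap_oligos`, …); see
`docs/methods.md` for the conventions and parameter defaults.

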