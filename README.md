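# guidescout

Off-target survey for CRISPR/SpCas9 guide RNA design by **exhaustive
variant-space mapping** against any user-supplied reference genome.

Most guide-design services predict off-targets by aligning the 20-nt spacer
to a genome while tolerating a few mismatches — and most cap the number of
reported loci, silently under-counting, and only offer a fixed catalogue of
genomes. guidescout inverts the search: for every candidate guide it
materialises *every* sequence the guide could productively pair with —
mismatches, DNA bulges and RNA bulges up to four edits — and matches those
variants against the genome **exactly**, with no reporting limit. Any
genome FASTA works as the reference, which matters for organisms absent
from the usual webservers.

## The method

For a guide of length *n* = 20 with at most *r* = 4 edits:

* **Substitutions** (mismatched base pairs): the Hamming ball
  S = Σᵢ₌₁..ᵣ 3ⁱ C(n, i) — 424,995 proper variants, 424,996 with the
  unedited center.
* **Deletions** (DNA bulges; the 5′-most base is never deleted):
  at most D = Σᵢ C(n−1, i) = 5,035 unique variants; the realised count is
  sequence-dependent — a poly-A guide gives just 4.
* **Insertions** (RNA bulges; 19 internal gaps + the spacer/PAM gap):
  I = r + Σᵢ Σⱼ≤ᵢ 3ʲ C(n−1+i, j) = 813,160 (61; 1,954; 43,726; 767,419
  for 1–4 insertions).

Together 1,243,190 variants per guide, and ×8 NRG PAMs
(AGG, TGG, GGG, CGG, AAG, TAG, GAG, CAG) → 9,945,520 exact search
patterns. Mapped substitution loci are scored per pair with the Hsu/MIT
position-weighted penalty and the empirical CFD factors, each summarised
per guide by the specificity aggregate 100·100/(100 + Σ singles); on-target
activity uses the Rule-Set-1 logistic over the 30-nt N₄-guide-NGG-N₃
context. All scores are on a 0–100 scale (higher off-target aggregate =
more specific guide). See `src/guidescout/data/PROVENANCE.md` for the
status of the bundled constants.

## Worked example

Build a deterministic 2×50-kb synthetic genome with four planted sites —
the design locus, a 2-mismatch NAG site, a 1-deletion site on the minus
strand and a 1-insertion site — then survey a query fragment containing
one guide:

```python
from guidescout.synthetic import PlantSpec, make_synthetic_genome, write_fasta
guide = "ATGCGTCATCAGACGTAGTC"
plants = [
    PlantSpec(guide, "substitution", (), "AGG", "chr1", 12000),
    PlantSpec(guide, "substitution", (("S",3,"T"),("S",9,"A")), "TAG", "chr1", 30500),
    PlantSpec(guide, "deletion", (("D",5,""),), "CGG", "chr2", 8200, "-"),
    PlantSpec(guide, "insertion", (("I",7,"G"),), "GGG", "chr2", 41000),
]
genome, truth = make_synthetic_genome(seed=11, length=50000, plants=plants,
                                      contigs=("chr1", "chr2"))
write_fasta(genome, "ref.fa")
```

```bash
$ guidescout run --genome ref.fa --input pate_fragment.fa --out results --r-max 2
completed 1 record(s) under results

$ cat results/exon1/outfiles/scores.tsv
guide  strand  start  end  sequence              pam  gc_percent  doench  subs  dels  ins  hsu_aggregate  cfd_aggregate  on_target
f1     +       12     32   ATGCGTCATCAGACGTAGTC  AGG  50.0        13.47   1     2     1   94.20          93.57          1
```

Reading the row: the guide occurs once in the genome with an NGG PAM
(`on_target` 1); one substitution locus (the planted 2-mismatch NAG site),
two deletion loci and one insertion locus were found. `dels` is 2, not 1,
because deleting the spacer's 3′-terminal base and appending a CAG PAM
reconstructs the design locus itself — a systematic self-match of the
deletion scheme visible in `align/f1.txt`:

```
> f1|del|D20|CAG chr1:12001:+ PAM=CAG
ATGCGTCATCAGACGTAGTC
|||||||||||||||||||-
ATGCGTCATCAGACGTAGT-
```

The aggregates 94.20 (Hsu) and 93.57 (CFD) reflect a single weak
substitution off-target; a guide with no substitution loci scores 100.
Each run writes four directories per query record — `align/` (pairwise
guide-to-variant alignments), `ot_maps/` (SAM hit maps), `single_guides/`
(per-guide FASTA for RNA secondary-structure tools), `outfiles/`
(`scores.tsv`, `raw.txt` with the 30-mer contexts for external
machine-learning scorers, `guides.fa`) — plus a step-by-step log.

The closed-form space sizes are available without a genome:

```bash
$ guidescout count --n 20 --r 4
substitutions (center excluded): 424,995
substitutions (center included): 424,996
deletions (maximum):             5,035
insertions per edit count:       61; 1,954; 43,726; 767,419
insertions (cumulative):         813,160
three-scheme total:              1,243,190
x 8 NRG PAMs:                    9,945,520
```

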