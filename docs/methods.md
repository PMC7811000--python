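# Methods

## Model of off-target recognition

SpCas9 tolerates imperfect guide:protospacer pairing: base mismatches, DNA
bulges (the genomic site is one to a few bases shorter than the spacer) and
RNA bulges (longer), typically up to about four defects over the 20-nt
spacer, provided an NRG PAM (NGG strongly, NAG weakly) flanks the site.
guidescout operationalises this as a *generate-then-match* model: the set of
genomic sequences a guide could cleave is enumerated explicitly — the
substitution Hamming ball plus deletion and insertion spaces up to `r`
edits, crossed with the eight NRG PAMs — and each member is located in the
genome by exact string matching on both strands. Because the tolerance is
pre-materialised, the matcher needs no mismatch model and no reporting cap;
the result is the complete set of candidate loci under the edit model.

This is a recall-oriented model: it deliberately over-predicts relative to
cellular assays (chromatin accessibility, dosage and kinetics are outside
the model), so its output is a ranking/filtering signal, not a cleavage
prediction.

## Guide discovery

Every 20-mer followed by NGG on either strand is a candidate; overlapping
candidates are all reported and named `f1..fF` / `r1..rR` in ascending
forward-strand coordinate per strand. Discovery uses NGG only; the weaker
NAG recognition enters through the variant PAM set, not through guide
design. Lowercase input is uppercased; any candidate whose spacer or PAM
contains an ambiguity code is dropped. Input shorter than 23 nt yields an
empty (logged) result. Coordinates are 0-based half-open internally and
1-based only in SAM.

## Variant spaces

* Substitutions: exact Hamming ball. Counter Σᵢ₌₁..ᵣ 3ⁱC(n,i); the
  `include_center` flag distinguishes the ball (424,996 at n=20, r=4) from
  the proper variants (424,995). The sets are nested in `r`, so the
  pipeline enumerates only the largest radius and classifies distance-0
  hits as on-target.
* Deletions: 1..r deletions over positions 2..20 (deleting the 5′ base
  would reproduce a suffix of the guide). The counter ΣᵢC(n−1,i) is an
  upper bound; the enumerator deduplicates strings (repeats collapse), so
  realised counts are sequence-dependent (4 for poly-A; 69 and 4,647 for
  the two worked-example guides).
* Insertions: single bases at 1..r of the 20 sites (19 internal gaps + the
  spacer/PAM gap; the 5′ gap is excluded, mirroring the deletion
  convention). The counter r + ΣᵢΣⱼ≤ᵢ3ʲC(n−1+i,j) reproduces the published
  per-i values; it is treated as a formula-level size, while the enumerator
  deduplicates, so per-sequence unique counts may fall below it.
  Deduplication is within scheme only; cross-scheme collisions are
  impossible (lengths differ) except between schemes of equal length, which
  do not occur here.
* Dedup keys on the spacer string; the canonical edit description kept is
  the first in (edit count, positions, bases) order, i.e. the
  lexicographically smallest. Enumeration order is deterministic
  (scheme → edit count → positions → bases → PAM) and streamed, so mapping
  consumes bounded batches (default 200,000 full-sites).
* Optional seed filter: keeps substitution variants whose edits all lie in
  the PAM-distal half (positions 1–10 from the 5′ end), reflecting the
  empirical intolerance of seed mismatches; off by default.

## Exact matching

Patterns are grouped by length; each contig is scanned once per distinct
length with a sliding window resolved by hash lookup, with each pattern
keyed both as itself (+) and as its reverse complement (−). Reverse-strand
hits are reported at the forward-strand leftmost coordinate; a palindromic
pattern yields one hit per orientation. Windows containing non-ACGT
characters match nothing. On ≤100-kb genomes the engine is tested for
exact equality against a naive all-offsets scan. Per-guide hits are
emitted as minimal SAM (`@HD`/`@SQ`; FLAG 0/16; CIGAR full-length M;
NM:i:0), parseable by pysam/samtools.

Counting is locus-based: distinct (contig, position, strand) per scheme,
with distance-0/NGG loci tallied separately as on-target. A locus-based
count was chosen over variants-that-map because one variant can match many
loci and each locus is one putative cleavage site.

## Scoring

* Hsu/MIT single score (substitution hits only, equal lengths required):
  100·Π(1−W[p])·1/(((19−d̄)/19)·4+1)·1/m², with W the 20 position weights,
  m mismatches and d̄ their mean pairwise distance (defined as 19 for
  m ≤ 1, neutralising the proximity term); m = 0 scores 100.
* CFD single score: 100·Π mismatch-factor(position, RNA base,
  template-strand DNA base)·PAM-factor. The table's DNA base is the base
  the guide RNA pairs with — the complement of the off-site protospacer
  base. NRG hits other than NGG are attenuated by the PAM factor; the Hsu
  system has no PAM factor (a documented asymmetry of the two systems).
* Aggregates: 100·100/(100+Σ singles) over substitution off-target loci
  (on-target excluded; indel hits enter only the counts, as the positional
  scores are undefined across lengths). Empty → 100; strictly
  anti-monotone in the hit set.
* On-target: Rule-Set-1 logistic over the 30-mer context ×100;
  'N'-padded contexts (guides at the query edge) report as missing (NA),
  with the row retained.

Constants are bundled as JSON package data. The Hsu weights and CFD PAM
factors are transcriptions of the small published constants; the 240-entry
CFD mismatch table and the Rule-Set-1 coefficients are labelled
reconstructions (`*_synthetic.json`) that preserve the published structure
and qualitative behaviour — see `src/guidescout/data/PROVENANCE.md`. The
RS1 file carries intercept, GC-count terms and mononucleotide weights;
dinucleotide interaction terms are omitted rather than fabricated, so
absolute on-target scores are approximate while remaining deterministic
and correctly bounded. Scoring correctness is asserted against an
independent straight-line reference implementation of each formula (shared
constants, independent code path) to 4 decimals.

## Synthetic data

The fixture generator emulates the only genome features the method is
sensitive to: exact occurrences of variant full-sites on either strand
embedded in a uniform ACGT background, with a truth table of expected
hits. Background accidental copies of planted sites are rejected by
re-sampling, so recovery tests are exhaustive. It does not emulate base
composition bias, repeats beyond chance, chromatin state or sequencing
artefacts — passing tests therefore demonstrate the combinatorics,
matching and scoring machinery, not biological predictive power on real
genomes. Default fixture scale in the suite is 1–4 kb backgrounds with
r ≤ 2 variant spaces (and the full r = 4 space for the desk-scale
enumeration checks); the pipeline itself is routinely run at 100 kb / r=2
in about a second, and the full r = 4, eight-PAM space (~10 M patterns per
guide) streams through the same code path in batches.

## Orchestration and determinism

The four steps (discover, map, score, align/report) run per query record;
records are distributed over a process pool (`workers`), each owning an
independent result tree, so `outfiles/` are byte-identical across worker
counts and repeated runs (no timestamps outside the log; fixed orderings
and number formats: scores at 2 decimals, GC at 1, '.' decimal separator,
missing values as NA). Per-record failures are isolated and logged without
aborting siblings. A flat key=value config file mirrors every CLI flag;
CLI wins on conflict.

## External reproduction (not run by the test suite)

The palm-oil thioesterase exon-1 case requires downloading GenBank
XM_010926998 (exon 1) and the EG5 assembly: running
`guidescout run --genome EG5.fa --input pate_exon1.fa --out results`
should discover 79 guides (35 forward, 44 reverse) and produce the
per-guide score distribution; the GUIDE-seq comparison additionally needs
GRCh37. These need multi-GB downloads and are documented here rather than
tested.

## Known limitations

* Exact matching of pre-materialised edits cannot represent a mismatch
  *combined* with a bulge in one site beyond the enumerated edit budget.
* The scoring constants' provenance caveats above apply; swap in verified
  published tables via `load_tables(data_dir=...)` for production use.
* The in-memory window scanner favours simplicity and testability; very
  large genomes (many hundreds of Mb) are feasible but slow in pure
  Python — the module boundary admits an external exact-matching engine
  with the same contract.
* r > 4 and guide lengths ≠ 20 are supported by the formulas and
  enumerators but are outside the validated default pipeline.
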