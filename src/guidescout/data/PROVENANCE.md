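# Scoring-constant provenance

- `hsu_weights.json` — the 20 position-specific mismatch penalty weights of the
  MIT/Hsu specificity matrix (5'→3', position 20 adjacent to the PAM), transcribed
  from the published matrix as reprinted across the guide-design literature.
- `cfd_pam.json` — cutting-frequency-determination PAM factors keyed on the two
  bases following N, transcribed from the published empirical fractions
  (e.g. NGG = 1, NAG = 7/27).
- `cfd_mismatch_synthetic.json` — **reconstruction, not a transcription.** The
  published CFD study provides a 240-entry empirical table (12 RNA:DNA mismatch
  types × 20 positions) in supplementary material that could not be obtained for
  verification when this file was built. The bundled values reproduce the table's
  structure and robust qualitative findings — tolerance decays from the PAM-distal
  to the PAM-proximal end, wobble pairings (rU:dG, rG:dT) are the most tolerated,
  purine:purine clashes the least — but individual entries are modelled, not
  measured. Replace this file with the published table for production use; the
  loader accepts any file with the same layout.
- `doench_rs1_synthetic.json` — **partial reconstruction.** Intercept, the two
  GC-count penalty terms and the position-specific mononucleotide weights of the
  Rule-Set-1 on-target logistic model over the 30-mer context; the published
  model's dinucleotide interaction terms are omitted rather than reconstructed.
  Scores remain a deterministic logistic on a 0–100 scale but are approximate
  relative to the full published model.

All factors lie in [0, 1] (weights in the RS1 file are logistic coefficients and
unbounded). Files are immutable package data; `scoring.load_tables()` can point
at replacements.
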