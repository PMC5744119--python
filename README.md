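# venomics

Integration toolkit for venom-gland transcriptome/proteome studies:
triage annotated transcripts into venom-component candidates, classify
and name them systematically, curate deconvolved intact-mass
fingerprints, match transcriptome-predicted masses against the venom
proteome, run in-silico tryptic digestion with sequence-coverage
reporting, and profile host-defense peptides with helical-wheel
descriptors. It is written for venomics groups who receive annotation
evidence (BLAST/Pfam/SignalP/ProP-style tables) and LC-MS output and
need the downstream integration to be reproducible and auditable.

## What it computes

- **Triage** — a transcript is a venom-candidate iff it (1) resembles a
  prior EST of the species, (2) carries a venom-associated domain, or
  (3) resembles a curated animal-toxin entry, each at e-value ≤ 1e-4
  (configurable). Systematic names are
  `<Species><Family><Subtype><NN>` (e.g. `TatNaTAlp01`); sequences
  identical to registry entries keep their published names.
- **Fingerprint curation** — deconvolved neutral masses [M] per RT bin,
  monoisotopic < 3000 Da and average above. Satellite peaks (Na/K/NH4
  adducts, oxidation, deamidation, dehydration, CO loss) are removed by
  delta rules to a fixed point; tolerances 0.02 Da (mono pairs) / 0.5 Da
  (otherwise).
- **Mass matching** — each predicted mature peptide's kind-selected
  theoretical mass pairs with its nearest same-kind fingerprint peak
  within 1.0 Da (default).
- **Digestion & coverage** — trypsin (cuts after K/R, not before P), ≤ 2
  missed cleavages; PSMs accepted at score > 25 with ≥ 2 fragments;
  coverage is the position-union of accepted peptides.
- **Descriptors** — Fauchère–Pliska hydrophobicity ⟨H⟩, Eisenberg
  hydrophobic moment μH = (1/N)·|Σₙ Hₙ·e^(i·n·δ)| at δ = 100°, and net
  charge (#R + #K) − (#D + #E).

See `docs/methods.md` for conventions, defaults and limitations.

## Worked example

The packaged reference fingerprint (135 deconvolved venom masses in
20-minute RT bins) and the five transcriptome-predicted masses that
match it:

```python
>>> from venomics import (reference_fingerprint, summarize_fingerprint,
...                       match_masses, reference_theoretical_entries)
>>> fp = reference_fingerprint()
>>> s = summarize_fingerprint(fp)
>>> s.count, s.min_rounded, s.median_rounded, s.max_rounded
(135, 1077, 4506, 16915)
>>> for m in match_masses(reference_theoretical_entries(), fp, tolerance=1.0):
...     print(m.peptide_id, m.theoretical_mass, m.experimental_mass, m.rt_bin)
TatCaTClc01 3788.48 3787.85 (80.0, 100.0)
TatKTxAlp10 3607.43 3606.6 (60.0, 80.0)
TatKTxAlp12 4114.86 4113.96 (80.0, 100.0)
TatNaTBet03 5196.79 5196.42 (80.0, 100.0)
TatNaTBet08 6195.85 6195.66 (180.0, 200.0)
```

The venom has 135 components between 1077 and 16,915 Da (median
4506 Da); five predicted mature peptides — a calcin, two β-sodium
toxins and two α-potassium toxins — are found intact in the venom, each
within 1 Da of its prediction and in one RT bin.

From the shell, the same pipeline over files:

```sh
venomics synth --seed 1 --out-dir demo        # synthetic transcriptome
venomics triage demo/evidence.tsv             # -> 160 / 200 flagged
venomics name demo/evidence.tsv demo/precursors.fasta \
    --precursor-table demo/precursors.tsv --registry demo/registry.yaml
venomics report demo/evidence.tsv             # family composition tally
```

`report` prints the composition
`{DBP: 41, HDP: 17, Enz: 55, La1: 7, PIn: 24, CRI: 8, Und: 8}` — 41
disulfide-bound channel toxins, 17 host-defense peptides, 55 enzymes,
7 La1-like peptides, 24 protease inhibitors, 8 CRISPs and 8 undefined
components. Further subcommands: `mass`, `fingerprint-filter`, `match`,
`digest`, `coverage`, `physchem`.

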