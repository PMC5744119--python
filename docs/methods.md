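# Methods

This note documents the models, conventions and numerical choices behind
`venomics`, and what the synthetic fixtures do and do not demonstrate.

## Scope and data model

The package integrates two views of a venom gland: the transcriptome
(assembled coding sequences with upstream annotation evidence) and the
proteome (a deconvolved intact-mass fingerprint plus search-engine PSM
tables). All similarity searching, domain identification, signal/propeptide
prediction, spectral deconvolution and PSM scoring are upstream: their
outputs are consumed as tables, never recomputed.

A precursor is modelled as a full amino-acid sequence with optional
signal, propeptide, mature and C-terminal-propeptide segments. Segments
are 0-based half-open intervals, ordered and disjoint; 1-based inclusive
coordinates appear only at the TSV boundary. A complete CDS must carry a
non-empty mature range, and the declared disulfide count may not exceed
half the mature cysteines.

## Transcript triage and nomenclature

A transcript is a venom-component candidate when any of three evidence
criteria holds at an e-value cut-off (default 1e-4): similarity to a prior
EST of the species, a venom-associated protein domain, or similarity to a
curated animal-toxin database entry. The flag is monotone in evidence —
extra hits can only confirm, never revoke.

The exact list of "distinctive venom domains" is a curated, editable
vocabulary (defensin, phospholipase, CAP/SCP, Kunitz, serpin, WAP, SVWC/
La1, generic toxin folds, hyaluronidase, peptidase families, ICK, DDH by
default); triage criterion 2 matches domain names against it by
case-insensitive substring.

Classification uses an ordered keyword rulebook (YAML, user-editable);
the first rule whose keywords all occur in the descriptor-plus-domain
text wins, giving deterministic tie-breaking, and unmatched candidates
fall back to Other/Undefined. Systematic names are
`<Species 3><Family 3><Subtype 3><NN>`; serials run 01, 02, … in
lexicographic transcript-id order (reproducible without expression
data), and a two-digit width is enforced unless widened explicitly. A
sequence identical to a registry entry keeps its published name —
exact-match lookup only, and registry precedence is absolute.
Composition tallies roll the three channel-toxin families (NaT, KTx,
CaT) into one disulfide-bound-peptide (DBP) figure, and split the Other
family into its La1-like, CRISP and Undefined subtypes, because that is
how venom-gland compositions are conventionally reported.

Percent identity is defined only for pre-aligned, equal-length sequences;
gaps count as mismatches. Reported values truncate at one decimal, the
convention used for the mature-level identities this package reports.

## Masses and the mass-kind rule

Residue masses (monoisotopic and average) and water derive from
pyteomics' elemental tables, so an unmodified peptide mass reproduces
ProtParam-style output: free termini, free cysteines. Corrections are
opt-in: C-terminal amidation (−0.98402 Da mono / −0.9847 avg, an OH→NH2
substitution) and −2.01565/−2.0159 Da per disulfide bond (two
hydrogens). The default *theoretical* mass of a predicted mature peptide
is therefore the uncorrected one — published theoretical tables for this
kind of data are ProtParam output, and the calcin row of the packaged
table (3788.48 theoretical vs 3787.85 experimental) is consistent with no
correction applied.

Deconvolved intact masses are monoisotopic below 3000 Da and average at
or above; exactly 3000.00 Da is average-kind ("below 3000" is strict).
The kind is a pure function of mass and governs two things: which
theoretical scale a fingerprint peak may be compared on (cross-kind
comparison is disallowed — it would bias every delta by the
mono/average offset, ~0.06%/kDa), and which pairing tolerance applies.

C-terminal α-amidation is called from the canonical Gly(+basic) signal
(G, GK, GR, GKR, GRR…) immediately following the mature peptide. Both
boundary conventions are handled and flagged: donor glycine at the start
of the C-terminal propeptide (mature reported unchanged) or included at
the end of the mature range (stripped from the reported mature). No
C-terminal propeptide means a negative call, never an error.

## Fingerprint curation

Satellite peaks are removed by delta rules: Na−H +21.98194, K−H
+37.95588, NH4 +17.02655 (adducts), oxidation +15.99491, deamidation
+0.98402 — the heavier peak is derived; dehydration −18.01056 and CO
loss −27.99491 — the lighter peak is derived. Values follow the Fiehn
adduct-calculator conventions and are user-extensible config.

Pairing tolerances default to 0.02 Da when both peaks are monoisotopic-
kind and 0.5 Da otherwise (deconvolution precision differs by an order
of magnitude between the regimes); both are configurable. Only
co-eluting peaks (same RT bin) are compared by default, since satellites
co-elute with their parent; cross-bin comparison is a flag. The filter
iterates to a fixed point, capped at 10 passes with a loud diagnostic
against pathological chains; within a pass a peak already marked as
derived may still anchor further removals, so chains (e.g. double
oxidation) collapse onto the genuine parent in one pass. Curation is
idempotent and conserving: survivors plus logged removals partition the
input.

Summaries use order statistics (even-count median = mean of the middle
pair); rounded values are reported alongside full precision. The mass
histogram bins at [k·w, (k+1)·w).

## Intact-mass matching

Each theoretical entry is compared, on its kind-selected scale, against
every same-kind fingerprint peak; the nearest peak within tolerance
yields one match (ties: smaller |delta|, then lower mass). One peak may
serve several entries — isobaric peptides exist and intact masses carry
no exclusivity claim. The default tolerance is 1.0 Da: the largest delta
in the packaged reference match table is 0.90 Da, so 1.0 Da reproduces
it exactly while staying below any plausible second candidate; it is a
CLI flag.

## Digestion, PSM acceptance and coverage

Tryptic cleavage is after K/R, suppressed before P (toggleable); the
digest enumerates all contiguous unions of 1..(max_missed+1) fragments
(default budget 2 missed cleavages, minimum length 1). Carbamidomethyl-C
(+57.02146 Da) is fixed — alkylation is part of the sample prep; Met
oxidation and amidation are enumerated as variable mass variants capped
at 3 variable sites per peptide.

PSMs are accepted when score > 25 (strict inequality) and fragment
count ≥ 2; both thresholds are parameters. FDR strata ("strict" 0.01 /
"relaxed" 0.05) are engine-side labels the filter can select on — no
decoy estimation here. Scores are engine-specific and treated as
dimensionless pass-through values. Coverage is the union of all exact
occurrences of accepted peptide sequences in the parent, as percent of
residues to one decimal (half-up); unlocatable peptides contribute
nothing but are logged.

## Physicochemical descriptors

Mean hydrophobicity uses the Fauchère–Pliska octanol/water scale (the
helical-wheel-server default; alternative scales loadable). The
hydrophobic moment is the per-residue-normalised first Fourier mode of
the hydrophobicity profile at δ = 100°/residue (α-helix; configurable
for 3₁₀/π). Net charge is (#R + #K) − (#D + #E) with His and termini
contributing zero; the no-termini convention is recorded in the profile
metadata. Published descriptor tables of this kind cannot be
regression-tested without the mature sequences, which are not printed;
the implementation is validated against closed forms (homopolymer
geometric sum, phase invariance, triangle inequality) and defines the
report format.

## Synthetic fixtures

Generators are pure functions of (spec, seed) using numpy's seeded
PCG64; identical inputs give identical outputs, and the seed is written
into fixture file headers.

- **Transcriptome**: 160 venom candidates in the composition
  {DBP 41, HDP 17, enzymes 55, La1 7, protease inhibitors 24, CRISP 8,
  undefined 8} — the composition reported for a deeply sequenced
  scorpion venom gland — expanded to subtypes by canonical weights
  (e.g. 13 NaTx = 3 α + 10 β; 21 KTx; 7 CaTx), plus 40 housekeeping
  decoys whose evidence must fail triage. Evidence rows are engineered
  so triage and classification recover the composition exactly; two
  generated matures are duplicated into the registry to exercise
  name-honouring. Residue composition is class-biased (cysteine
  placement for DBPs, cationic/hydrophobic 13-mers with GKR propeptides
  for the short antimicrobials) — cosmetic realism only.
- **Fingerprint**: ~30 base masses spaced ≥ 120 Da apart (more than
  twice the largest delta rule), half of which receive one co-eluting
  satellite at a rule offset with jitter below half the pairing
  tolerance. The spacing guarantees no cross-base pair can match any
  rule, so curation must remove exactly the planted satellites. A
  negative-control mode displaces satellites past the tolerance (using
  the well-isolated sodium-adduct delta so displacement cannot alias a
  neighbouring rule) and expects zero removals.
- **PSM tables**: tryptic peptides sampled from parents with scores and
  fragment counts straddling the acceptance thresholds, including exact
  boundary cases; expected coverage ships with the fixture from a direct
  position-union count.

What passing these tests shows: the rules are implemented exactly as
specified, at realistic composition and scale. What they do not show:
robustness to real annotation noise (conflicting descriptors, chimeric
transcripts), real deconvolution error structure (the jitter model is
uniform and bounded), or engine score calibration — those live upstream
of this package's contract.

## Problem sizes and determinism

The default test suite runs the full 160-transcript fixture, 20-seed
artifact-recovery sweeps, exhaustive digestion oracles on 200-mers and
1000-peptide mass property checks — a few seconds end to end, chosen so
the whole pipeline is exercised at the study's own scale. Property
tests are derandomised Hypothesis profiles; everything else is seeded.
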