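# Methods

This note describes, in the package's own words, how each quantity it
reports is computed and which choices are conventions rather than
consequences of the data.

## Coordinate convention

All motif and fragment positions are expressed relative to the
translation initiation site (TIS, the A of the ATG) in a signed system
with **no position 0**: +1 is the A of the ATG and −1 the base
immediately upstream. Promoter tables in the plant literature use this
convention, and under it their span arithmetic is exact:

* an inclusive span `start..end` on one side of the TIS has
  `end − start + 1` bases; a span crossing the TIS has `−start + end`
  bases (the "missing" zero is skipped), so −272..+51 is 323 bp;
* a 14-base box starting at −110 ends at −97; a 15-base box starting at
  −670 ends at −656; a 2-base span starting at −1 ends at +1.

`awbox.coords` implements the conversions between this system and
0-based promoter-local indices; every scanner hit carries both.

## The motif pattern and scanning

The canonical AW box is the 14-mer `CNTNG(N)₇CG`: conserved C, T, G at
positions 1, 3, 5 and CG at 13–14, with nine variable positions
N₁–N₉. A window matches if and only if the five conserved positions
match; the ambiguity character `N` in input sequence never matches.
The minus strand is scanned by testing the reverse complement of each
coding-strand window. Hits report the occupied span on the coding
strand and the matched sequence as read 5'→3' on the matched strand,
which is how published motif tables list minus-strand boxes.

**Non-canonical (insertion) variants.** WRI1 binding was demonstrated
for a 15-mer that matches the canonical pattern after deletion of one
internal extra base. The scanner therefore also tests every 15-mer
window for internal single-base deletions (offsets 2..14; deleting a
terminal base would merely re-anchor the conserved ends). When the
extra base sits in a run of identical bases its position is ambiguous;
the scanner deterministically reports the 5'-most legal offset, which
can differ from an annotation that names a chemically specific base in
the run. The packaged KAR2 record stores the annotated offset (4),
while the scanner reports offset 2 for the same window; both describe
the same set of sequences.

Under a uniform background a canonical box matches by chance about
once per 4⁵ = 1024 bp per strand (five fixed positions), so analyses
compare scanner output against ground truth rather than assuming
incidental hits are absent.

## Position matrices

From the N = 18 canonical 14-mers that clearly bound WRI1 in EMSA:

* **PFM** — exact per-position base counts.
* **PPM** — `(count + a) / (N + 4a)` with pseudocount `a`. Two PPMs are
  kept deliberately: the raw one (`a = 0`), because zero counts are the
  signal behind the forbidden-base rule, and a smoothed one
  (`a = 0.5` by default) that feeds the log-odds matrix.
* **PWM** — `log2(probability / background)` per cell, with uniform
  background by default (the genome-wide base composition is not part
  of the shipped data); zero probabilities map to −∞.

**Forbidden bases and bias.** At each variable position the bases with
zero count in the PFM are reported as forbidden, and the modal base as
the bias (ties are kept as sets, never broken arbitrarily). On the
shipped bound set this yields: G forbidden at N₁, N₂, N₈, N₉; A at N₄;
C at N₃, N₆; none at N₅ or N₇; bias C at N₂ (13/18) and A at N₆
(12/18). With 18 training sequences a zero count is suggestive, not
proof — the binomial chance of missing a base whose true frequency is
0.05 in 18 draws is ≈ 0.40 — which is why the classifier reports the
rule it applied rather than a probability.

## IUPAC consensus

The consensus is derived from the raw PPM with two documented
thresholds. Each variable position emits the minimal IUPAC code over
the bases with probability ≥ `include_threshold` (default **0.2**),
except that a position whose top base reaches `collapse_threshold`
(default **0.6**) emits that single base ("bias collapse" — this is
what writes C at N₂ and A at N₆). Conserved positions always emit
their base. On the shipped bound set the defaults give
`CHTCGWKWAYWYCG`.

The thresholds are conventions: include = 0.2 means "seen in at least
roughly a fifth of the bound set" (4/18), suppressing singleton
observations from the degeneracy code, and collapse = 0.6 writes a
single letter only where a clear majority exists. Neither "include
anything observed" nor a 0.5 collapse reproduces a consensus of this
shape on these data: the first inflates positions with singletons
(e.g. a single C observed at N₅ would turn W into H), the second
collapses positions with a 10/18 plurality that the degenerate code
should keep. An alternative `inclusion` mode (no collapse) is provided
for sensitivity analysis.

## Classifier

The mechanism is the forbidden-base rule: a candidate 14-mer is
predicted **not-bindable** iff it carries a forbidden base at any
variable position; every violated position contributes one explicit
reason string. Three modes exist: `strict-forbidden` (the rule the
data directly support), `allowed-profile` (equivalent by construction,
divergent only if the allowed sets are edited by hand) and
`pwm-threshold` (log-odds score against a user-supplied bit threshold;
no experimentally anchored default exists). When a candidate carries
coordinates, a distance gate (default: |start| ≤ 500 bp from the TIS,
inclusive) applies as well, reflecting the observation that active
boxes sit close to the TIS, usually within the 5'-UTR.

15-mer insertion variants are *not* forced through the canonical rule:
binding of such a box is an experimental precedent, but the matrices
are trained on canonical 14-mers only, so these are labelled bindable
with an explicit "non-canonical, bindable-precedent" note instead of a
rule-based verdict.

**Evaluation.** Fitting on the 18 bound boxes and scoring all 52
EMSA-tested canonical boxes gives sensitivity 18/18 = 1.0 (by
construction: no training sequence can carry a forbidden base) and
specificity 22/25 = 0.88. The three false positives are exactly the
unbound boxes without any forbidden base — the rule has no grounds to
reject them, and the evaluation table marks them as such. The nine
"smear" boxes (ambiguous lanes suggesting weak binding) are held out
of both classes and reported separately.

## Mutagenesis and probes

`mutate_n_position` substitutes a base at a named variable position
(N₁–N₉) of a 14-mer or of a 15-mer insertion variant (where the
position is located in the underlying canonical frame, skipping the
extra base); `substitute_inserted_base` replaces the extra base
itself. These reproduce the published mutant probe sequences
byte-exactly. `build_probe` assembles a double-stranded probe of
length `len(box) + 2 × flank` with explicit or seeded-random flanks
(box + 5-bp flanks → 24 bp).

## Synthetic data

The generator draws i.i.d. background from a configurable base
composition with `numpy.random.default_rng(seed)` and overwrites it
with planted boxes (from the packaged bound/unbound pools, explicit
sequences, forbidden-base decoys or insertion variants) at controlled
TIS distances and strands, enforcing non-overlap and returning exact
ground-truth records. The same seed and configuration give
byte-identical output. The generator makes no claim of biological
realism — no dinucleotide structure, no TATA context, no positional
preference beyond what is requested — it exists to exercise every
pipeline stage with known truth.

## Fixture provenance and limitations

The packaged TSV transcribes the published motif tables (sequence,
strand, TIS-relative span, 5'-UTR membership) and the EMSA outcomes
described in the accompanying text. Three table-printed end
coordinates are internally inconsistent with a 14-mer span and were
recomputed from the start coordinate and motif length; the affected
rows say so in their `source` field. One position is printed
differently in two places (−610 vs −613); the table value is used.

The bound training set contains 18 members. Seventeen are unambiguous
from the text; the published roster exists only as figure colouring,
so the 18th (a KASIII-2g box) is a reconstruction consistent with
every constraint the text imposes (the gene is named as carrying an
active box, and the resulting matrix reproduces the published
forbidden/bias table and consensus exactly). The record is flagged
`PROVISIONAL` in its `source` field. All fixture-dependent numbers in
the tests and this note are asserted against the shipped fixture with
this caveat.
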