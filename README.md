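# awbox

Analysis of the **AW box**, the 14-bp cis-regulatory element
`CNTNG(N)₇CG` bound by WRINKLED1-class (WRI1) transcription factors in
the promoters of plant fatty-acid synthesis genes.

The package ships a transcription of the published motif inventory for
the sunflower plastidial fatty-acid synthesis pathway — 79 motif
instances across ~30 genes, 52 of them tested for WRI1 binding by
electrophoretic mobility shift assay (EMSA) — and implements the full
analysis chain on top of it:

* **Coordinate arithmetic** in the signed, no-zero convention used by
  promoter tables: −1 abuts +1 (the A of the ATG), so a fragment
  spanning −272..+51 is 323 bp long and a 14-bp box starting at −110
  ends at −97.
* **Strand-aware scanning** for canonical boxes and for the
  non-canonical 15-mer variants that match after deletion of one
  internal "extra" base — a form shown experimentally to bind.
* **Position matrices** (PFM / PPM / PWM) built from the 18 motifs that
  clearly bound WRI1 in EMSA, with a twist specific to small bound
  sets: a base *never observed* at a variable position is reported as
  **forbidden** there, and its presence predicts non-binding.
* **An IUPAC consensus** (`CHTCGWKWAYWYCG` under the documented default
  thresholds) and a text sequence logo.
* **A rule-based classifier** built on the forbidden-base mechanism,
  plus the point-mutagenesis operations used to design EMSA probes.
* **A seeded synthetic-promoter generator** with planted boxes, decoys
  and ground-truth records, so the whole pipeline is testable offline.

## Worked example

The core analysis is exposed as a model/results pair. `fit()` derives
the matrices, the forbidden-base report, the consensus and a
classifier from the packaged bound set:

```python
>>> from awbox import fixtures, model
>>> records = fixtures.load_fixtures()
>>> res = model.BindingSiteModel.from_records(records).fit()
>>> print(res.summary())
AW-box binding-site model
======================================================
training sequences (clear EMSA positives): 18
background (ACGT): (0.25, 0.25, 0.25, 0.25)
PWM pseudocount: 0.5
consensus (include>=0.2, collapse>=0.6): CHTCGWKWAYWYCG

pos  forbidden  bias (prob)
 N1  G          AC (0.39)
 N2  G          C (0.72)
 N3  C          T (0.44)
 N4  A          T (0.44)
 N5  -          AT (0.39)
 N6  C          A (0.67)
 N7  -          C (0.39)
 N8  G          T (0.56)
 N9  G          C (0.56)
...
```

Scanning a promoter reports hits on both strands with promoter-local
and TIS-relative coordinates:

```python
>>> from awbox.scan import PromoterSequence, scan_canonical
>>> p = PromoterSequence("FATA1-1g",
...                      "A"*40 + "CCTCGTGCATATCG" + "A"*96 + "ATGGCA",
...                      tis_index=150)
>>> scan_canonical(p)[0]
MotifHit(gene_id='FATA1-1g', local_start=40, local_end=54,
         tis_start=-110, tis_end=-97, strand='+', variant='canonical',
         matched_seq='CCTCGTGCATATCG', insertion_offset=None)
```

Classification explains every rejection in terms of the forbidden-base
rule:

```python
>>> res.predict("CTTGGAGTACTCCG")
Prediction(label='not-bindable',
           reasons=('G at N2 is forbidden (allowed: ACT)',),
           score=None, note=None)
```

Evaluated against all 52 EMSA-tested canonical boxes, the rule recovers
every bound box (sensitivity 18/18 = 1.0) and rejects 22 of 25 unbound
ones (specificity 0.88); the three false positives are exactly the
unbound boxes that carry no forbidden base, and the 9 ambiguous
("smear") boxes are held out of both classes.

## Command line

```
awbox fixtures    # list / export the packaged motif inventory
awbox scan        # scan FASTA promoters, write hit TSV / BED6
awbox matrices    # PFM/PPM/PWM, consensus, MEME-minimal, text logo
awbox classify    # label candidate boxes with a fitted profile
awbox evaluate    # fit on bound fixtures, evaluate on all tested ones
awbox simulate    # seeded synthetic promoters with planted boxes
awbox reproduce   # the full published analysis, end to end
```

Exit codes: 0 success, 2 configuration error, 3 data error. Logging
goes to stderr; data go to files or stdout only.

## Caveats

* The definitive roster of the 18-member bound training set was
  published only as figure colouring; 17 members are unambiguous from
  the text and one is provisional. The provisional record is flagged in
  its `source` field, and `docs/methods.md` explains the choice.
* EMSA outcomes are wet-lab data: the package consumes them as labels
  and cannot re-derive them. All other numbers in this README are
  computed from the shipped fixtures at runtime.

See `docs/methods.md` for the methods note (coordinate convention,
matrix construction, consensus thresholds, classifier mechanics and
the synthetic generator's scope).
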