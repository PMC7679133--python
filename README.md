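# hhquant

Quantitative analysis of Hedgehog-pathway Ci-155 gradients at the
anterior–posterior (AP) border of *Drosophila* wing imaginal discs.

## The problem

Hedgehog (Hh), spreading anteriorly from the posterior compartment, does two
things to the transcription factor Cubitus interruptus: it **inhibits
processing** of full-length Ci-155 to the truncated repressor Ci-75, and at
high pathway activity it **stimulates reduction** of Ci-155 levels
(attributed to full proteolysis). In a fixed disc one only sees their sum —
the steady-state Ci-155 stripe — so neither graded process is directly
visible. Processing-resistant Ci variants break the degeneracy: their
profile declines toward the boundary purely because of Hh-stimulated
reduction. `hhquant` implements the resulting decomposition for
experimentalists quantifying immunofluorescence profiles:

1. **Profiles** — extract column-mean intensity traces from rectangular
   ROIs, smooth (5-point centered moving average), detect ptc-lacZ
   landmarks (baseline, initial rise, 50% rise, peak), align replicate
   discs on the reporter maximum (which marks the compartment boundary),
   and average with per-position SEM.
2. **Decomposition** — with the resistant-variant average C_R(x) and its
   anterior maximum C_max, the reduction profile is

       R(x) = C_max − C_R(x)

   and the *no-reduction* curve, the Ci-155 profile that processing
   inhibition alone would produce, is

       C_nored(x) = C_WT(x) + R(x).

   The inhibition fraction φ(x) = (C_nored(x) − C_ant)/(C_top − C_ant)
   yields the positions where processing is first, 50% and fully
   inhibited, plus two summary fold changes.
3. **Clone metrics** — the mosaic-clone normalizations
   (clone − anterior)/(AP border − anterior) for the ptc reporter,
   (region − posterior)/(AP border − posterior) for Ci-155, plain ratios,
   mean ± SEM summaries, and paired / Welch t-tests with the
   figure marks (`*` p<0.001, `#` p<0.05).
4. **Synthetic discs** — a steady-state kinetic generator,
   C(x) = s_syn / (k_basal + k_proc(x) + k_deg(x)) with Hill-function
   responses to an exponential Hh gradient, genotype presets (WT,
   processing-resistant, weakly activatable, Su(fu)-null), replicate
   jitter and noise, clone-region tables and rendered TIFF images — all
   with ground truth attached, so every inference stage is testable by
   parameter recovery. An *additive* mode makes the decomposition exactly
   invertible for machine-precision round-trip tests.

## Worked example

```sh
python examples/02_decompose_profiles.py
```

simulates three noisy discs each for WT and two processing-resistant
variants, aligns them, and decomposes:

```
anterior maximum of resistant Ci-155 :  1035.3 a.u.
reduction at the boundary            :   625.0 a.u.
processing first inhibited at        :  -48.0 um
processing 50% inhibited at          :  -27.0 um
processing fully inhibited at        :  -15.0 um
fold reduction by the boundary       :  2.52
fold span of processing inhibition   :  3.37
```

Positions are in µm with the boundary at 0. The resistant variants sit at
~1000 a.u. anteriorly (no processing) and lose ~625 a.u. to Hh-stimulated
reduction by the boundary (over two-fold); the inferred processing
inhibition is graded from −48 µm to −15 µm and spans over two-fold — and
its half-point lies anterior of the reporter's half-rise, i.e. processing
inhibition responds to lower Hh levels than target-gene activation.

The other examples cover the generator (`01`), clone statistics (`03`) and
image/ROI extraction (`04`). A thin CLI wraps the same stages:
`hhquant simulate|extract|landmarks|align|decompose|clones|report`
(see `hhquant --help`); every run writes its resolved config and a log for
reproducibility.

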