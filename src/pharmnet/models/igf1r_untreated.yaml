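# Continuous Petri-net reconstruction of the untreated (diseased) IGF-1R /
# ER-alpha signaling network.
#
# Reconstruction choices (the published wiring is figure-only; every choice
# below is this package's own):
#   - activation steps are unit-weight token transfers along the cascade
#     IGF -> IGF1R -> IRS1 -> PI3k -> Akt -> ERalpha;
#   - IGF is a constant boundary source (read arc: pre+post), marking 5;
#   - ERalpha feeds back onto IGF1R (positive feedback); first-order
#     turnover on IGF1R and ERalpha keeps that loop stable;
#   - tumor-suppressor genes (p53, BRCA1, Mdm2) have basal source-transition
#     synthesis inhibited by ERalpha (threshold 1) and first-order turnover;
#     Mdm2 negatively regulates p53 via an Mdm2-catalysed degradation;
#   - TSG initial markings are 0.2 (suppressed species start below the
#     signaling baseline of 1) so that recovery is expressible as a fold
#     increase;
#   - every mass-action rate constant is 1; all arc weights are 1.
places:
  - {name: IGF, initial: 5.0}
  - {name: IGF1R, initial: 1.0}
  - {name: IRS1, initial: 1.0}
  - {name: PI3k, initial: 1.0}
  - {name: Akt, initial: 1.0}
  - {name: ERalpha, initial: 1.0}
  - {name: p53, initial: 0.2}
  - {name: BRCA1, initial: 0.2}
  - {name: Mdm2, initial: 0.2}
transitions:
  - {name: igf1r_activation, law: mass_action, k: 1.0}
  - {name: irs1_activation, law: mass_action, k: 1.0}
  - {name: pi3k_activation, law: mass_action, k: 1.0}
  - {name: akt_activation, law: mass_action, k: 1.0}
  - {name: era_activation, law: mass_action, k: 1.0}
  - {name: era_igf1r_feedback, law: mass_action, k: 1.0}
  - {name: igf1r_turnover, law: mass_action, k: 1.0}
  - {name: era_turnover, law: mass_action, k: 1.0}
  - {name: p53_synthesis, law: mass_action, k: 1.0, source: true}
  - {name: brca1_synthesis, law: mass_action, k: 1.0, source: true}
  - {name: mdm2_synthesis, law: mass_action, k: 1.0, source: true}
  - {name: mdm2_p53_degradation, law: mass_action, k: 1.0}
  - {name: p53_turnover, law: mass_action, k: 1.0}
  - {name: brca1_turnover, law: mass_action, k: 1.0}
  - {name: mdm2_turnover, law: mass_action, k: 1.0}
arcs:
  - [IGF, igf1r_activation, pre, 1.0]
  - [IGF, igf1r_activation, post, 1.0]
  - [IGF1R, igf1r_activation, post, 1.0]
  - [IGF1R, irs1_activation, pre, 1.0]
  - [IRS1, irs1_activation, post, 1.0]
  - [IRS1, pi3k_activation, pre, 1.0]
  - [PI3k, pi3k_activation, post, 1.0]
  - [PI3k, akt_activation, pre, 1.0]
  - [Akt, akt_activation, post, 1.0]
  - [Akt, era_activation, pre, 1.0]
  - [ERalpha, era_activation, post, 1.0]
  - [ERalpha, era_igf1r_feedback, pre, 1.0]
  - [IGF1R, era_igf1r_feedback, post, 1.0]
  - [IGF1R, igf1r_turnover, pre, 1.0]
  - [ERalpha, era_turnover, pre, 1.0]
  - [p53, p53_synthesis, post, 1.0]
  - [BRCA1, brca1_synthesis, post, 1.0]
  - [Mdm2, mdm2_synthesis, post, 1.0]
  - [p53, mdm2_p53_degradation, pre, 1.0]
  - [Mdm2, mdm2_p53_degradation, pre, 1.0]
  - [Mdm2, mdm2_p53_degradation, post, 1.0]
  - [p53, p53_turnover, pre, 1.0]
  - [BRCA1, brca1_turnover, pre, 1.0]
  - [Mdm2, mdm2_turnover, pre, 1.0]
inhibitory_arcs:
  - [ERalpha, p53_synthesis, 1.0]
  - [ERalpha, brca1_synthesis, 1.0]
  - [ERalpha, mdm2_synthesis, 1.0]
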