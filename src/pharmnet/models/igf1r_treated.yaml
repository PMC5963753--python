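# Continuous Petri-net reconstruction of the fulvestrant-treated IGF-1R /
# ER-alpha signaling network: the untreated net (see igf1r_untreated.yaml)
# plus the inhibitor and the PTEN arm.
#
# Additional reconstruction choices:
#   - fulvestrant is a constant boundary place (marking 5, matching IGF's
#     scale; sustained dosing) whose only interactions are inhibitory arcs
#     onto the IGF1R, IRS1 and ERalpha activation transitions (threshold 1);
#   - PTEN induction is a source transition inhibited by ERalpha with
#     threshold 0.3 instead of the default 1: ERalpha dips transiently below
#     1 (but stays above 0.56) in the untreated regime, so a threshold of 1
#     would mis-trigger the PTEN arm without treatment, and a threshold
#     crossed tangentially stalls the hard-switch integrator;
#   - PTEN de-phosphorylates PI3k and Akt (PTEN-catalysed removal
#     transitions) and catalyses synthesis of p53, BRCA1 and Mdm2;
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
  - {name: fulvestrant, initial: 5.0}
  - {name: PTEN, initial: 0.2}
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
  - {name: pten_synthesis, law: mass_action, k: 1.0, source: true}
  - {name: pten_turnover, law: mass_action, k: 1.0}
  - {name: pten_pi3k_inactivation, law: mass_action, k: 1.0}
  - {name: pten_akt_inactivation, law: mass_action, k: 1.0}
  - {name: pten_p53_activation, law: mass_action, k: 1.0}
  - {name: pten_brca1_activation, law: mass_action, k: 1.0}
  - {name: pten_mdm2_activation, law: mass_action, k: 1.0}
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
  - [PTEN, pten_synthesis, post, 1.0]
  - [PTEN, pten_turnover, pre, 1.0]
  - [PI3k, pten_pi3k_inactivation, pre, 1.0]
  - [PTEN, pten_pi3k_inactivation, pre, 1.0]
  - [PTEN, pten_pi3k_inactivation, post, 1.0]
  - [Akt, pten_akt_inactivation, pre, 1.0]
  - [PTEN, pten_akt_inactivation, pre, 1.0]
  - [PTEN, pten_akt_inactivation, post, 1.0]
  - [PTEN, pten_p53_activation, pre, 1.0]
  - [PTEN, pten_p53_activation, post, 1.0]
  - [p53, pten_p53_activation, post, 1.0]
  - [PTEN, pten_brca1_activation, pre, 1.0]
  - [PTEN, pten_brca1_activation, post, 1.0]
  - [BRCA1, pten_brca1_activation, post, 1.0]
  - [PTEN, pten_mdm2_activation, pre, 1.0]
  - [PTEN, pten_mdm2_activation, post, 1.0]
  - [Mdm2, pten_mdm2_activation, post, 1.0]
inhibitory_arcs:
  - [ERalpha, p53_synthesis, 1.0]
  - [ERalpha, brca1_synthesis, 1.0]
  - [ERalpha, mdm2_synthesis, 1.0]
  - [fulvestrant, igf1r_activation, 1.0]
  - [fulvestrant, irs1_activation, 1.0]
  - [fulvestrant, era_activation, 1.0]
  - [ERalpha, pten_synthesis, 0.3]
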