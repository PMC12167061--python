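# Disease parameters for the AUC-ceiling report.
#
# h2_twin: liability-scale heritabilities from twin studies (AD value excludes
# the APOE effect).
#
# prevalence: EDITABLE PLACEHOLDERS. The analysis calls for nationally reported
# (e.g. CDC) prevalence figures, which are not bundled here; the values below
# are round order-of-magnitude stand-ins a user should replace with their own
# sourced estimates.
#
# h2_gwas: EDITABLE PLACEHOLDERS. Five summary-statistic heritability estimates
# per disease (the slots correspond to five alternative estimation tools).
# The synthetic values below are plausible fractions of the twin estimate and
# exist only so the report pipeline runs end to end.
diseases:
  - label: CAD
    prevalence: 0.065
    h2_twin: 0.55
    h2_gwas: [0.14, 0.18, 0.21, 0.24, 0.28]
  - label: T2D
    prevalence: 0.105
    h2_twin: 0.72
    h2_gwas: [0.17, 0.22, 0.26, 0.31, 0.36]
  - label: BreastCancer
    prevalence: 0.13
    h2_twin: 0.27
    h2_gwas: [0.07, 0.09, 0.10, 0.11, 0.13]
  - label: AD
    prevalence: 0.10
    h2_twin: 0.49
    h2_gwas: [0.06, 0.08, 0.10, 0.13, 0.16]
  - label: Asthma
    prevalence: 0.08
    h2_twin: 0.70
    h2_gwas: [0.10, 0.15, 0.20, 0.25, 0.30]
  - label: Obesity
    prevalence: 0.42
    h2_twin: 0.75
    h2_gwas: [0.20, 0.25, 0.30, 0.34, 0.38]
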