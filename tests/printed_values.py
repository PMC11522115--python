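"""Published reference values used by the validation tests.

``PRINTED_DECISION_TABLE`` is the bedside decision tool at cutoff -7.2
exactly as published: per nadir temperature (deg C, rows -30..-53) the
cell for each unsuccessful-application count 0..3. "A" = always test,
"N" = no test within the displayed TTI range, an integer = the minimal
test-triggering TTI in seconds.
"""

A, N = "A", "N"

PRINTED_DECISION_TABLE: dict[int, list] = {
    -30: [A, A, A, A],
    -31: [A, A, A, A],
    -32: [A, A, A, A],
    -33: [A, A, A, A],
    -34: [A, A, A, A],
    -35: [A, A, A, A],
    -36: [A, A, A, A],
    -37: [10, A, A, A],
    -38: [20, A, A, A],
    -39: [30, 5, A, A],
    -40: [40, 15, A, A],
    -41: [50, 25, A, A],
    -42: [60, 35, 10, A],
    -43: [70, 45, 20, A],
    -44: [80, 55, 30, 5],
    -45: [90, 65, 40, 15],
    -46: [N, 75, 50, 25],
    -47: [N, 85, 60, 35],
    -48: [N, 95, 70, 45],
    -49: [N, N, 80, 55],
    -50: [N, N, 90, 65],
    -51: [N, N, N, 75],
    -52: [N, N, N, 85],
    -53: [N, N, N, 95],
}

# operating points as published: confusion counts of the validation cohort
# and projected counts of the derivation cohort at each cutoff
VALIDATION_CONFUSION_67 = dict(tp=14, fn=23, fp=67, tn=546)   # cutoff -6.7
VALIDATION_CONFUSION_72 = dict(tp=27, fn=10, fp=131, tn=482)  # cutoff -7.2
VALIDATION_PREVALENCE = 41 / 774
DERIVATION_SENS_72 = 29 / 40       # printed 72.50%
DERIVATION_SPEC_72 = 1 - 83 / 381  # printed 78.22%
DERIVATION_PREVALENCE = 0.0922
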