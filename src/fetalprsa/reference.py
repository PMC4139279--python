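"""Validation constants for the seven-animal ovine UCO cohort.

Per-subject time constants (seconds) of the fetal RR response to cord
occlusion onset (``stim``) and release (``rec``), as reported for the
seven near-term sheep that passed beat-quality control.  They serve two
purposes: fixed inputs for validating the summary/statistics machinery,
and the empirical ranges from which the synthetic generator draws
per-subject time constants.
"""

COHORT_TAU_STIM_S = (9.63, 46.17, 34.56, 14.22, 34.65, 12.46, 11.76)
COHORT_TAU_REC_S = (6.46, 5.22, 4.30, 3.38, 7.88, 4.36, 5.61)
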