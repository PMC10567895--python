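# Anatomical priors.
#
# mean_pfl_mm: population mean palpebral fissure length (ex-en), the "known
#   length" proxy A.  Default 30.7 mm follows Farkas's adult facial
#   anthropometric norms; override with sex- or ancestry-specific means when
#   appropriate.
# sd_pfl_mm: population SD of the fissure length (1.2 mm), the quantity that
#   makes the mean usable as a proxy.
# pcs_*: population mean/SD of the pupil-chord-to-stomion distance used by
#   the synthetic-subject generator (nominal adult values; the estimator
#   itself never needs them because PCS is calibrated per subject).
# depth_extent_mm: axial near-to-far feature separation used by the
#   perspective-tolerance metric (nominal value; artifact definition).
mean_pfl_mm: 30.7
sd_pfl_mm: 1.2
pcs_mean_mm: 65.0
pcs_sd_mm: 3.5
depth_extent_mm: 100.0
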