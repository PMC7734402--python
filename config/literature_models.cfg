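# Literature metric-vs-OGT regression lines (metric_on_ogt orientation:
# metric = intercept + slope * OGT[C]).
#
# The comparative surveys these lines come from publish the plots; transcribe
# the coefficients from the cited sources before use.  Entries with a blank
# slope or intercept are ignored by read_model_config, so this file is safe
# to pass as-is.  Units: gc_16s_molpct in mol% (fraction x 100), cvp_bias in
# percentage points, ivywrel as a fraction.

# 16S rRNA G+C vs OGT, 406-prokaryote survey
gc_16s_molpct.slope =
gc_16s_molpct.intercept =
gc_16s_molpct.n = 406

# average CvP vs OGT, fitted on 4 Thermotogae-lineage genomes
cvp_bias.slope =
cvp_bias.intercept =
cvp_bias.n = 4

# IVYWREL vs OGT, 86-prokaryote survey
ivywrel.slope =
ivywrel.intercept =
ivywrel.n = 86
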