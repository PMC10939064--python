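# PLACEHOLDER — tibial reference cells intentionally unpopulated.
# Published per-region tibial standards are not available to this package;
# populate this file from your own healthy cohort (kneecart build-reference)
# before grading tibial regions. Until then tibial regions report UNGRADED.
sex,side,region,mean_mm,sd_mm
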