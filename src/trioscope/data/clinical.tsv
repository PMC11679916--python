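# Digitized reference-cohort clinical summary: printed cohort-level counts and percentages.
# The source reports three non-identical consanguinity figures; all are stored as printed:
#   consanguinity_pct (clinical table, 56), consanguineous_families / consanguineous_pct
#   (cohort description, 59 families = 57%), consanguineous_families_alt (discussion, 56).
key	value	unit
n_families	104	count
n_probands	104	count
n_male	69	count
n_female	35	count
male_pct	66	percent
female_pct	34	percent
consanguinity_pct	56	percent
consanguineous_families	59	count
consanguineous_pct	57	percent
consanguineous_families_alt	56	count
ethnicity_pct	100	percent
autism_pct	100	percent
language_speech_delay_pct	78	percent
behavioural_problems_pct	60	percent
developmental_delays_pct	42	percent
intellectual_disability_pct	13	percent
epilepsy_pct	12	percent
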