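patient_id	field	value
A01203	sex	M
A02903	sex	F
A05503	sex	M
A06603	sex	M
A08203	sex	M
A01203	age_of_onset_months	30
A02903	age_of_onset_months	5
A05503	age_of_onset_months	7
A06603	age_of_onset_months	5
A08203	age_of_onset_months	3
A01203	hemiplegia_start_months	30
A02903	hemiplegia_start_months	11
A05503	hemiplegia_start_months	7
A06603	hemiplegia_start_months	8
A08203	hemiplegia_start_months	3
A01203	hemiplegia_duration_days	0.01~4
A02903	hemiplegia_duration_days	2~7
A05503	hemiplegia_duration_days	0.01~3
A06603	hemiplegia_duration_days	1~2
A08203	hemiplegia_duration_days	2~3
A01203	hemiplegia_frequency_per_month	3~15
A02903	hemiplegia_frequency_per_month	1~2
A05503	hemiplegia_frequency_per_month	2~3
A06603	hemiplegia_frequency_per_month	2
A08203	hemiplegia_frequency_per_month	2~3
A01203	developmental_delay	+
A02903	developmental_delay	+
A05503	developmental_delay	+
A06603	developmental_delay	+
A08203	developmental_delay	Uncertain
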