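subject_id	visit_index	behavioural_class	eeg_cf	fmri_cf
PS01	1	MCS-	neg	neg
PS01	2	MCS+	pos	neg
PS02	1	MCS-	neg	pos
PS03	1	VS/UWS	pos	pos
PS04	1	VS/UWS	neg	neg
PS05	1	MCS+	neg	neg
PS06	1	MCS-	pos	not_done
PS07	1	MCS+	pos	neg
PS08	1	MCS+	pos	neg
PS08	2	eMCS	pos	neg
PS09	1	MCS+	pos	pos
PS10	1	eMCS	pos	pos
PS11	1	eMCS	pos	neg
PS11	2	MCS+	pos	pos
PS12	1	MCS+	pos	pos
PS12	2	MCS+	neg	neg
PS13	1	MCS-	pos	pos
PS14	1	VS/UWS	pos	neg
PS15	1	MCS-	neg	neg
PS16	1	MCS-	neg	neg
PS17	1	VS/UWS	pos	not_done
PS18	1	MCS+	neg	pos
PS19	1	MCS+	neg	neg
PS20	1	eMCS	pos	neg
PS20	2	eMCS	pos	neg
PS20	3	eMCS	pos	neg
PS21	1	eMCS	pos	not_done
PS22	1	VS/UWS	neg	neg
PS23	1	eMCS	neg	not_done
PS23	2	eMCS	neg	neg
PS24	1	VS/UWS	neg	not_done
HC01	1	HC	not_done	not_done
HC02	1	HC	not_done	not_done
HC03	1	HC	not_done	not_done
HC04	1	HC	not_done	not_done
HC05	1	HC	not_done	not_done
HC06	1	HC	not_done	not_done
HC07	1	HC	not_done	not_done
HC08	1	HC	not_done	not_done
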