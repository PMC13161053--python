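# Default 115-gene phycobilisome / photosystem / respiration panel.
# Symbols not individually enumerated in the panel source are shipped as
# clearly marked placeholder slots so category totals remain 115.
gene_symbol	category	model_id	eukaryote_specific
apcA	phycobilisome	apcA	0
apcB	phycobilisome	apcB	0
apcC	phycobilisome	apcC	0
apcD	phycobilisome	apcD	0
apcE	phycobilisome	apcE	0
apcF	phycobilisome	apcF	0
cpcA	phycobilisome	cpcA	0
cpcB	phycobilisome	cpcB	0
cpcC	phycobilisome	cpcC	0
cpcD	phycobilisome	cpcD	0
cpcE	phycobilisome	cpcE	0
cpcF	phycobilisome	cpcF	0
cpcG	phycobilisome	cpcG	0
cpeA	phycobilisome	cpeA	0
cpeB	phycobilisome	cpeB	0
cpeC	phycobilisome	cpeC	0
cpeD	phycobilisome	cpeD	0
cpeE	phycobilisome	cpeE	0
cpeR	phycobilisome	cpeR	0
cpeS	phycobilisome	cpeS	0
cpeT	phycobilisome	cpeT	0
cpeU	phycobilisome	cpeU	0
cpeY	phycobilisome	cpeY	0
cpeZ	phycobilisome	cpeZ	0
psaG	photosystem	psaG	1
psaH	photosystem	psaH	1
psaN	photosystem	psaN	1
psaO	photosystem	psaO	1
psbQ	photosystem	psbQ	1
psbR	photosystem	psbR	1
psbW	photosystem	psbW	1
photosystem_slot_01	photosystem	photosystem_slot_01	0
photosystem_slot_02	photosystem	photosystem_slot_02	0
photosystem_slot_03	photosystem	photosystem_slot_03	0
photosystem_slot_04	photosystem	photosystem_slot_04	0
photosystem_slot_05	photosystem	photosystem_slot_05	0
photosystem_slot_06	photosystem	photosystem_slot_06	0
photosystem_slot_07	photosystem	photosystem_slot_07	0
photosystem_slot_08	photosystem	photosystem_slot_08	0
photosystem_slot_09	photosystem	photosystem_slot_09	0
photosystem_slot_10	photosystem	photosystem_slot_10	0
photosystem_slot_11	photosystem	photosystem_slot_11	0
photosystem_slot_12	photosystem	photosystem_slot_12	0
photosystem_slot_13	photosystem	photosystem_slot_13	0
photosystem_slot_14	photosystem	photosystem_slot_14	0
photosystem_slot_15	photosystem	photosystem_slot_15	0
photosystem_slot_16	photosystem	photosystem_slot_16	0
photosystem_slot_17	photosystem	photosystem_slot_17	0
photosystem_slot_18	photosystem	photosystem_slot_18	0
photosystem_slot_19	photosystem	photosystem_slot_19	0
photosystem_slot_20	photosystem	photosystem_slot_20	0
photosystem_slot_21	photosystem	photosystem_slot_21	0
photosystem_slot_22	photosystem	photosystem_slot_22	0
photosystem_slot_23	photosystem	photosystem_slot_23	0
photosystem_slot_24	photosystem	photosystem_slot_24	0
photosystem_slot_25	photosystem	photosystem_slot_25	0
photosystem_slot_26	photosystem	photosystem_slot_26	0
photosystem_slot_27	photosystem	photosystem_slot_27	0
photosystem_slot_28	photosystem	photosystem_slot_28	0
photosystem_slot_29	photosystem	photosystem_slot_29	0
photosystem_slot_30	photosystem	photosystem_slot_30	0
photosystem_slot_31	photosystem	photosystem_slot_31	0
photosystem_slot_32	photosystem	photosystem_slot_32	0
photosystem_slot_33	photosystem	photosystem_slot_33	0
photosystem_slot_34	photosystem	photosystem_slot_34	0
photosystem_slot_35	photosystem	photosystem_slot_35	0
photosystem_slot_36	photosystem	photosystem_slot_36	0
photosystem_slot_37	photosystem	photosystem_slot_37	0
cydA	electron_transport_respiration	cydA	0
cydB	electron_transport_respiration	cydB	0
cydX	electron_transport_respiration	cydX	0
petA	electron_transport_respiration	petA	0
petB	electron_transport_respiration	petB	0
petC	electron_transport_respiration	petC	0
petD	electron_transport_respiration	petD	0
petL	electron_transport_respiration	petL	0
petM	electron_transport_respiration	petM	0
petG	electron_transport_respiration	petG	0
petN	electron_transport_respiration	petN	0
ctaC	electron_transport_respiration	ctaC	0
ctaD	electron_transport_respiration	ctaD	0
ctaE	electron_transport_respiration	ctaE	0
ctaF	electron_transport_respiration	ctaF	0
sdhC	electron_transport_respiration	sdhC	0
sdhD	electron_transport_respiration	sdhD	0
hoxE	electron_transport_respiration	hoxE	0
etc_slot_01	electron_transport_respiration	etc_slot_01	0
etc_slot_02	electron_transport_respiration	etc_slot_02	0
etc_slot_03	electron_transport_respiration	etc_slot_03	0
etc_slot_04	electron_transport_respiration	etc_slot_04	0
etc_slot_05	electron_transport_respiration	etc_slot_05	0
etc_slot_06	electron_transport_respiration	etc_slot_06	0
etc_slot_07	electron_transport_respiration	etc_slot_07	0
etc_slot_08	electron_transport_respiration	etc_slot_08	0
etc_slot_09	electron_transport_respiration	etc_slot_09	0
etc_slot_10	electron_transport_respiration	etc_slot_10	0
etc_slot_11	electron_transport_respiration	etc_slot_11	0
etc_slot_12	electron_transport_respiration	etc_slot_12	0
etc_slot_13	electron_transport_respiration	etc_slot_13	0
etc_slot_14	electron_transport_respiration	etc_slot_14	0
etc_slot_15	electron_transport_respiration	etc_slot_15	0
etc_slot_16	electron_transport_respiration	etc_slot_16	0
etc_slot_17	electron_transport_respiration	etc_slot_17	0
etc_slot_18	electron_transport_respiration	etc_slot_18	0
etc_slot_19	electron_transport_respiration	etc_slot_19	0
etc_slot_20	electron_transport_respiration	etc_slot_20	0
etc_slot_21	electron_transport_respiration	etc_slot_21	0
etc_slot_22	electron_transport_respiration	etc_slot_22	0
etc_slot_23	electron_transport_respiration	etc_slot_23	0
etc_slot_24	electron_transport_respiration	etc_slot_24	0
etc_slot_25	electron_transport_respiration	etc_slot_25	0
etc_slot_26	electron_transport_respiration	etc_slot_26	0
etc_slot_27	electron_transport_respiration	etc_slot_27	0
etc_slot_28	electron_transport_respiration	etc_slot_28	0
etc_slot_29	electron_transport_respiration	etc_slot_29	0
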