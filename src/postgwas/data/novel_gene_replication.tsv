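gene	n_evidence	traits	min_p_rep
SPCS1	3	SBP,PP	2.39e-2
GRAP	3	DBP	5.35e-3
NT5DC2	3	PP	1.62e-2
FAM212A	3	SBP,DBP	1.07e-2
RPS6KB1	2	SBP,PP	4.61e-7
HOXA7	2	SBP,DBP,PP	2.03e-2
NIP7	2	DBP	7.13e-3
CCDC97	2	DBP,PP	4.42e-4
CENPV	2	DBP	1.43e-2
MAP1A	2	DBP	2.03e-3
TTC16	2	SBP	5.00e-4
LTBP3	2	SBP,PP	1.70e-2
NSG2	2	SBP,DBP	5.09e-5
RP5-874C20.3	2	DBP,PP	1.55e-8
HIST1H2BH	2	SBP,DBP	5.48e-3
TPM2	2	DBP	1.75e-2
RNU6-510P	2	SBP,PP	1.45e-10
AC116366.6	2	SBP,DBP	2.33e-2
RP11-464F9.1	2	SBP,DBP,PP	7.30e-4
RP11-464F9.9	2	SBP,DBP,PP	9.45e-4
RNU6-415P	2	PP	5.32e-4
RP11-10A14.3	2	SBP,DBP,PP	3.21e-7
RP11-148O21.4	2	SBP,DBP	1.95e-4
RP11-59H1.3	2	SBP,PP	1.07e-2
RP3-473L9.4	2	SBP,DBP,PP	2.00e-5
ZNF234	2	SBP,DBP	4.04e-2
AF131215.9	2	SBP,DBP,PP	8.34e-6
RP11-148O21.6	2	SBP,DBP	1.35e-3
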