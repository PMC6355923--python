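# Lipid species observed in ischemic mouse brain MSI, shorthand -> elemental formula.
# adducts: comma-separated tags understood by strokemsi.lipids.adduct_mz
name	formula	adducts	polarity
PC(32:0)	C40H80NO8P	+H,+Na,+K	positive
PC(34:1)	C42H82NO8P	+H,+Na,+K	positive
PC(36:1)	C44H86NO8P	+H,+Na,+K	positive
LPC(16:0)	C24H50NO7P	+H,+Na,+K	positive
PI(38:4)	C47H83O13P	-H	negative
PIP(38:4)	C47H84O16P2	-H	negative
PIP2(38:4)	C47H85O19P3	-H	negative
PS(40:6)	C46H78NO10P	-H	negative
FA(16:0)	C16H32O2	-H	negative
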