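name	start	end	category
N-terminal	1	432	terminal
C-terminal	684	838	terminal
Ank-1	112	152	ankyrin
Ank-2	153	199	ankyrin
Ank-3	200	246	ankyrin
Ank-4	247	282	ankyrin
Ank-5	283	331	ankyrin
Ank-6	332	359	ankyrin
TM-1	433	454	TM
Loop-1	455	479	loop
TM-2	480	495	TM
Loop-2	496	509	loop
TM-3	510	531	TM
Loop-3	532	542	loop
TM-4	543	569	TM
Loop-4	570	576	loop
CBD	577	593	motif
TM-5	577	596	TM
Loop-5	597	623	loop
Pore	624	645	other
Loop-6	646	654	loop
TM-6	655	683	TM
TAD-1	684	721	motif
TRP-Box	696	701	motif
TBS-1	710	730	motif
TAD-2	752	772	motif
TBS-2	770	797	motif
Cam-BR	767	801	motif
PIP-2	778	819	motif
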