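pair	lnRV:AGLA17	lnRV:SOD1	lnRH:AGLA17	lnRH:SOD1	lnRtheta:AGLA17	lnRtheta:SOD1
EasternFin-Istoben	*	*	n.s.	n.s.	*	n.s.
EasternFin-Yakutian	*	**	*	**	**	*
EasternFin-UkrainianGrey	**	**	*	*	**	*
EasternFin-Kholmogory	*	**	*	*	*	*
WesternFin-Istoben	**	*	**	**	*	*
WesternFin-Yakutian	**	**	*	*	*	**
WesternFin-UkrainianGrey	*	*	**	*	*	*
WesternFin-Kholmogory	*	*	*	*	*	**
NorthernFin-Istoben	*	n.s	*	n.s.	n.s.	*
NorthernFin-Yakutian	*	n.s.	n.s.	*	n.s.	n.s.
NorthernFin-UkrainianGrey	**	*	n.s.	n.s.	n.s.	n.s.
NorthernFin-Kholmogory	*	n.s.	n.s.	*	n.s.	n.s.
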