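marker	pair	T_ivanbureschi	T_macedonicus	T_cristatus	T_dobrogicus	T_carnifex_I	T_carnifex_B	T_anatolicus	T_karelinii	T_pygmaeus	T_marmoratus
TiY-95401	short	o	.	.	.	.	.	.	.	.	.
TiY-95401	long	+	+	+	x	o	o	+	o	+	+
TiY-105918	short	o	.	.	.	.	.	.	.	.	.
TiY-105918	long	o	.	.	.	.	.	.	.	.	.
TiY-106308	short	+	+	o	.	.	.	.	.	.	.
TiY-106308	long	+	o	o	.	.	.	.	.	.	.
TiY-137941	short	+	+	o	.	.	.	.	.	.	.
TiY-137941	long	+	+	+	+	o	+	+	o	x	x
TiY-201098	short	+	+	o	.	.	.	.	.	.	.
TiY-201098	long	o	.	.	.	.	.	.	.	.	.
TiY-254147	short	o	.	.	.	.	.	.	.	.	.
TiY-254147	long	o	.	.	.	.	.	.	.	.	.
TiY-301991	short	o	.	.	.	.	.	.	.	.	.
TiY-301991	long	o	.	.	.	.	.	.	.	.	.
TiY-384959	short	+	+	+	x	+	+	+	+	+	+
TiY-384959	long	+	+	+	x	x	x	+	x	x	x
TiY-416318	short	o	.	.	.	.	.	.	.	.	.
TiY-416318	long	o	.	.	.	.	.	.	.	.	.
TiY-442534	short	+	+	o	.	.	.	.	.	.	.
TiY-444315	short	+	+	+	x	+	x	+	o	x	x
TiY-444315	long	o	.	.	.	.	.	.	.	.	.
TiY-817010	short	+	+	o	.	.	.	.	.	.	.
TiY-817010	long	+	+	+	x	o	+	+	o	+	+
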