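rt_s	name
9	1,4-Dioxane-2,6-dione
38	Butane, 2-methyl-
42	Isoprene
47	4-Penten-1-ol
53	Pentane, 2-methyl-
62	1-Pentene, 2-methyl-
65	n-Hexane
72	1-Pentanol, 2-methyl-
115	Hexane, 3-methyl-
137	Heptane
154	Cyclohexane, methyl-
158	1-Pentanol, 2-ethyl-4-methyl-
175	Pentane, 2,2,3-trimethyl-
197	2,4-dimethylhexane
209	Pentane, 2,3,4-trimethyl-
214	Pentane, 2,3,3-trimethyl-
221	Hexane, 2,3-dimethyl-
230	Hexane, 2,3-dimethyl-
239	Heptane, 2,5-dimethyl-
249	Hexane, 2,2,4-trimethyl-
255	Hexane, 2,2,5-trimethyl-
260	1-Octene
266	Tetrachloroethylene
267	4-Octene, (Z)-
271	4-Octene, (E)-
276	Octane
283	Heptane, 3,3-dimethyl-
288	2-Heptene, 3-methyl-
295	2-Octene
304	Hexane, 2,3,5-trimethyl-
316	Heptane, 2,4-dimethyl-
327	Octane, 2-methyl-
341	Heptane, 2,5-dimethyl-
362	Hexane, 2,3,4-trimethyl-
372	4,6-Octadiyn-3-one, 2-methyl-
376	Heptane, 2,3-dimethyl-
387	Octane, 4-methyl-
394	Cyclopentane, 2-ethyl-1,1-dimethyl-
412	Heptane, 2,2,4-trimethyl-
422	Octane, 2,2-dimethyl-
441	Octane, 3,3-dimethyl-
470	Hexane, 2,2,5,5-tetramethyl-
482	Heptane, 2,3,6-trimethyl-
502	a-Pinene
504	Cyclohexene, 4-methylene-1-(1-methylethyl)-
527	4-Octene, 2,6-dimethyl-,[S-(E)]-
533	2-Undecanethiol, 2-methyl-
558	Octane, 4-ethyl-
565	5-Ethyldecane
601	Decyl octyl ether
609	Decane, 2,6,7-trimethyl-
616	Decane, 2,4,6-trimethyl-
624	Dodecane, 1-fluoro-
630	Decane, 2,2-dimethyl-
656	Decane, 2,6,8-trimethyl-
665	2,2,7,7-Tetramethyloctane
675	Decane, 2,5,9-trimethyl-
696	Heptane, 5-ethyl-2,2,3-trimethyl-
717	Decane, 2,6,7-trimethyl-
735	Undecane, 3,6-dimethyl-
768	Dodecane, 2,7,10-trimethyl-
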