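id,known_survival_days,event,cause,homed,livestock_killed_per_year,litters,success_printed,comments
Aju01,519,death,hyaena,no,0,,yes,stable sibling group
Aju02,426,censored,,no,0,4,yes,stable sibling group
Aju03,322,death,accident,no,0,,no,suspected natural accident
Aju07,11,censored,recapture,no,0,,no,recaptured; later death from renal failure in captivity
Aju17,960,censored,,no,0,,yes,mating suspected
Aju18,14,death,other,no,0,,no,shock/exhaustion
Aju19,13,death,hyaena,no,0,,no,split upon release
Aju20,67,censored,collar_failure,no,0,,unknown,split upon release; collar failure
Aju26,112,censored,collar_failure,no,0,,unknown,collar failure
Aju29,840,censored,,no,0,2,yes,split from Aju30 upon release
Aju30,290,censored,collar_failure,no,0,,unknown,accidentally trapped and re-released
Aju34,991,death,shot,no,0,,yes,shot due to severe front leg injury
Aju38,636,death,hyaena,no,0,,yes,mating suspected
Aju40,19,death,hyaena,no,0,,no,
Aju41,205,death,shot,no,0,,no,killed due to lack of fear of humans
Aju42,71,death,shot,no,11,,no,killed due to lack of fear of humans
Aju43,71,death,shot,no,11,,no,killed due to lack of fear of humans
Aju44,71,death,shot,no,11,,no,killed due to lack of fear of humans
Aju56,680,censored,,no,0,3,yes,
Aju58,427,death,shot,no,1,5,yes,killed due to livestock depredation
Aju59,19,death,trap,no,0,,no,sub-adults survived after female's death
Aju65,371,censored,,yes,0,,no,stable coalition; homed
Aju66,590,censored,,yes,0,,no,stable coalition; homed
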