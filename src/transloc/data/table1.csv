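id,sex,age_class_years,mass_kg,capture_region,release_area,release_year,background,captivity_days,translocation_distance_km,release_mode,acclimation_weeks,social_unit,habituation,transmitter
Aju01,F,2-3,37,Otjozondjupa,NRNR,2008,indiscriminate,10,526,hard,,sibling_group,wild,VHF
Aju02,F,2-3,33,Otjozondjupa,NRNR,2008,indiscriminate,10,526,hard,,sibling_group,wild,ID
Aju03,M,2-3,38,Otjozondjupa,NRNR,2008,indiscriminate,10,526,hard,,sibling_group,wild,VHF
Aju07,F,7-9,33,Khomas,NRNR,2008,livestock_raider,61,331,hard,,mother_with_2_offspring,wild,VHF
Aju17,M,5-7,44,Otjozondjupa,NRNR,2009,livestock_raider,175,490,hard,,individual,wild,GPS
Aju18,F,5-7,43,Otjozondjupa,NRNR,2009,livestock_raider,157,470,hard,,individual,wild,GPS
Aju19,M,3-5,49,Khomas,KWR,2009,indiscriminate,62,312,hard,,artificial_group,wild,VHF
Aju20,F,6-8,37,Omaheke,KWR,2009,indiscriminate,37,396,hard,,artificial_group,wild,GPS
Aju26,M,2-3,44,Otjozondjupa,FOC,2009,indiscriminate,12,182,hard,,individual,wild,GPS
Aju29,F,3-4,38,Otjozondjupa,NRNR,2010,orphan_rehab,596,482,soft,10,artificial_group,semi,VHF
Aju30,M,3-4,41,Otjozondjupa,NRNR,2010,orphan_rehab,446,431,soft,10,artificial_group,semi,GPS
Aju34,M,3-4,43,Omaheke,FOC,2010,indiscriminate,47,137,hard,,individual,wild,VHF
Aju38,M,3-4,37,Khomas,SGF,2011,indiscriminate,153,259,soft,18,individual,wild,GPS
Aju40,F,3-4,37,Otjozondjupa,NDL,2012,indiscriminate,1184,289,soft,38,sibling_group,habituated,GPS
Aju41,F,3-4,38,Otjozondjupa,NDL,2012,indiscriminate,1184,289,soft,38,sibling_group,habituated,VHF
Aju42,M,3-4,29,Otjozondjupa,SNGR,2011,orphan_rehab,1055,816,soft,18.5,artificial_group,habituated,VHF
Aju43,M,3-4,32,Otjozondjupa,SNGR,2011,orphan_rehab,1106,806,soft,18.5,artificial_group,habituated,GPS
Aju44,M,3-4,32,Otjozondjupa,SNGR,2011,orphan_rehab,1055,816,soft,18.5,artificial_group,habituated,VHF
Aju56,F,5-7,45,Otjozondjupa,FOC,2012,indiscriminate,169,402,hard,,mother_with_3_offspring,wild,GPS
Aju58,F,5-7,40,Otjozondjupa,NRNR,2012,indiscriminate,260,372,soft,4,mother_with_2_offspring,semi,GPS
Aju59,F,4-6,38,Khomas,SNGR,2012,indiscriminate,272,659,soft,1,mother_with_3_offspring,semi,GPS
Aju65,M,6-7,51,Khomas,FOC,2012,indiscriminate,1,71,hard,,male_coalition,wild,VHF
Aju66,M,6-7,53,Khomas,FOC,2012,indiscriminate,2,71,hard,,male_coalition,wild,GPS
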