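study_id,location,followup_years,total,cases,design
Andre 2007 (DESIR),France,3,3545,309,cumulative_incidence
Schindhelm 2007 (Hoorn),Netherlands,6,1097,226,cumulative_incidence
Jo 2009 (HPC),Korea,4,21535,802,cumulative_incidence
Nakanishi 2004 (Office Workers),Japan,7,2957,608,cumulative_incidence
Xu 2011 (Shanghai),China,4,681,180,cumulative_incidence
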