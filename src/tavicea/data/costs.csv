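item,euros
tavi_procedure,30634
savr_procedure,24675
atrial_fibrillation,1090
balloon_valvuloplasty,3962
endocarditis,10573
hosp_as,6876
hosp_hf,3051
major_bleeding,3891
major_stroke,19624
major_vascular,3392
myocardial_infarction,8353
new_pacemaker,4756
renal_replacement,1381
tia,2967
acute_pulmonary_oedema,3802
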