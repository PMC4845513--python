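# Central-carbon reaction map template: numbered label -> reaction id(s).
#
# Each entry maps a labelled central-carbon step (glycolysis, oxidative
# pentose phosphate pathway, TCA cycle, mitochondrial electron transport)
# to the reaction id(s) carrying it in a given model.  A label may list
# several ids: their fluxes are summed, which is how lumped alternatives
# (e.g. a single AOX/COX pair standing in for separate ETC complexes) are
# reconciled across models.  Edit the ids per model; labels whose ids are
# absent from a model are reported as N/A, not zero.
"01_hexokinase": []
"02_glucose6P_isomerase": []
"03_phosphofructokinase_ATP": []
"04_phosphofructokinase_PPi": []
"05_aldolase": []
"06_triose_phosphate_isomerase": []
"07_GAPDH_NAD": []
"08_GAPDH_NADP_nonphosphorylating": []
"09_phosphoglycerate_kinase": []
"10_phosphoglycerate_mutase": []
"11_enolase": []
"12_pyruvate_kinase": []
"13_pyruvate_dehydrogenase": []
"14_citrate_synthase": []
"15_aconitase": []
"16_isocitrate_dehydrogenase": []
"17_2OG_dehydrogenase": []
"18_succinate_thiokinase": []
"19_complex_II": []
"20_fumarase": []
"21_malate_dehydrogenase": []
"22_glucose6P_dehydrogenase": []
"23_6P_gluconolactonase": []
"24_6P_gluconate_dehydrogenase_NADP": []
"25_6P_gluconate_dehydrogenase_NAD": []
"26_ribuloseP_3_epimerase": []
"27_ribose5P_isomerase": []
"28_transketolase_1": []
"29_transketolase_2": []
"30_transaldolase": []
"31_PEP_carboxylase": []
"32_ETC_complex_I_or_AOX": []
"33_ETC_complex_IV_or_COX": []
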