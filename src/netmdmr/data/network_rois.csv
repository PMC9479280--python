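network,region,hemisphere,column,display_name
FPN,superior_frontal_gyrus_prefrontal,left,superior_frontal_gyrus_prefrontal_left,superior frontal gyrus (prefrontal cortex)
FPN,superior_frontal_gyrus_prefrontal,right,superior_frontal_gyrus_prefrontal_right,superior frontal gyrus (prefrontal cortex)
FPN,middle_frontal_gyrus_posterior,left,middle_frontal_gyrus_posterior_left,middle frontal gyrus (posterior segment)
FPN,middle_frontal_gyrus_posterior,right,middle_frontal_gyrus_posterior_right,middle frontal gyrus (posterior segment)
FPN,middle_frontal_gyrus_dorsal_prefrontal,left,middle_frontal_gyrus_dorsal_prefrontal_left,middle frontal gyrus (dorsal prefrontal cortex)
FPN,middle_frontal_gyrus_dorsal_prefrontal,right,middle_frontal_gyrus_dorsal_prefrontal_right,middle frontal gyrus (dorsal prefrontal cortex)
FPN,inferior_frontal_gyrus_pars_opercularis,left,inferior_frontal_gyrus_pars_opercularis_left,inferior frontal gyrus (pars opercularis)
FPN,inferior_frontal_gyrus_pars_opercularis,right,inferior_frontal_gyrus_pars_opercularis_right,inferior frontal gyrus (pars opercularis)
FPN,inferior_frontal_gyrus_pars_orbitalis,left,inferior_frontal_gyrus_pars_orbitalis_left,inferior frontal gyrus (pars orbitalis)
FPN,inferior_frontal_gyrus_pars_orbitalis,right,inferior_frontal_gyrus_pars_orbitalis_right,inferior frontal gyrus (pars orbitalis)
FPN,precentral_gyrus,left,precentral_gyrus_left,precentral gyrus
FPN,precentral_gyrus,right,precentral_gyrus_right,precentral gyrus
FPN,supramarginal_gyrus,left,supramarginal_gyrus_left,supramarginal gyrus
FPN,supramarginal_gyrus,right,supramarginal_gyrus_right,supramarginal gyrus
FPN,angular_gyrus,left,angular_gyrus_left,angular gyrus
FPN,angular_gyrus,right,angular_gyrus_right,angular gyrus
FPN,precuneus,left,precuneus_left,precuneus
FPN,precuneus,right,precuneus_right,precuneus
FPN,inferior_temporal_gyrus,left,inferior_temporal_gyrus_left,inferior temporal gyrus
FPN,inferior_temporal_gyrus,right,inferior_temporal_gyrus_right,inferior temporal gyrus
FPN,middle_occipital_gyrus,left,middle_occipital_gyrus_left,middle occipital gyrus
FPN,middle_occipital_gyrus,right,middle_occipital_gyrus_right,middle occipital gyrus
DMN,posterior_cingulate_cortex,left,posterior_cingulate_cortex_left,posterior cingulate cortex
DMN,posterior_cingulate_cortex,right,posterior_cingulate_cortex_right,posterior cingulate cortex
DMN,rostral_anterior_cingulate_cortex,left,rostral_anterior_cingulate_cortex_left,rostral anterior cingulate cortex
DMN,rostral_anterior_cingulate_cortex,right,rostral_anterior_cingulate_cortex_right,rostral anterior cingulate cortex
DMN,precuneus,left,precuneus_left,precuneus
DMN,precuneus,right,precuneus_right,precuneus
DMN,cuneus,left,cuneus_left,cuneus
DMN,cuneus,right,cuneus_right,cuneus
DMN,middle_temporal_gyrus,left,middle_temporal_gyrus_left,middle temporal gyrus
DMN,middle_temporal_gyrus,right,middle_temporal_gyrus_right,middle temporal gyrus
DMN,angular_gyrus,left,angular_gyrus_left,angular gyrus
DMN,angular_gyrus,right,angular_gyrus_right,angular gyrus
DMN,gyrus_rectus,left,gyrus_rectus_left,gyrus rectus
DMN,gyrus_rectus,right,gyrus_rectus_right,gyrus rectus
DMN,middle_frontal_orbital_gyrus,left,middle_frontal_orbital_gyrus_left,middle frontal orbital gyrus
DMN,middle_frontal_orbital_gyrus,right,middle_frontal_orbital_gyrus_right,middle frontal orbital gyrus
DMN,superior_frontal_gyrus_prefrontal,left,superior_frontal_gyrus_prefrontal_left,superior frontal gyrus (prefrontal cortex)
DMN,superior_frontal_gyrus_prefrontal,right,superior_frontal_gyrus_prefrontal_right,superior frontal gyrus (prefrontal cortex)
DMN,superior_frontal_gyrus_pole,left,superior_frontal_gyrus_pole_left,superior frontal gyrus (frontal pole)
DMN,superior_frontal_gyrus_pole,right,superior_frontal_gyrus_pole_right,superior frontal gyrus (frontal pole)
DMN,amygdala,left,amygdala_left,amygdala
DMN,amygdala,right,amygdala_right,amygdala
DMN,parahippocampal_gyrus,left,parahippocampal_gyrus_left,parahippocampal gyrus
DMN,parahippocampal_gyrus,right,parahippocampal_gyrus_right,parahippocampal gyrus
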