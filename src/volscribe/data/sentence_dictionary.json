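{
 "templates": {
  "hemispheric": "There is {side} hemispheric atrophy.",
  "prominent": "The atrophy is prominent in the {lobes} lobe.",
  "prominent_sided": "The {side} hemispheric atrophy is prominent in the {lobes} lobe.",
  "specific": "There is {side} {lobes} lobe specific atrophy.",
  "direct_atrophy": "The {structure} has atrophy.",
  "enlargement": "The {structure} is enlarged.",
  "enlargement:deep_sulci": "The deep sulci are widened."
 },
 "terms": {
  "hippocampus_L": "left hippocampus",
  "hippocampus_R": "right hippocampus",
  "amygdala_L": "left amygdala",
  "amygdala_R": "right amygdala",
  "caudate_L": "left caudate",
  "caudate_R": "right caudate",
  "lateral_ventricle_L": "left lateral ventricle",
  "lateral_ventricle_R": "right lateral ventricle",
  "third_ventricle": "third ventricle",
  "deep_sulci": "deep sulci",
  "cerebellum": "cerebellum",
  "brainstem": "brainstem"
 }
}
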