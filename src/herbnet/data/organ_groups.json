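{
  "uterus": ["uterus", "uterus corpus"],
  "placenta_fetus": ["placenta", "fetal brain", "fetal liver", "fetal lung", "fetal thyroid"],
  "hypothalamus_pituitary": ["hypothalamus", "pituitary"],
  "smooth_muscle": ["smooth muscle"],
  "pituitary": ["pituitary"],
  "whole_blood": ["whole blood"]
}
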