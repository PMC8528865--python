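male	female
prostate	ovary
penile	uterine
penis	uterus
man	woman
men	women
masculine	feminine
he	she
him	her
his	hers
boy	girl
boys	girls
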