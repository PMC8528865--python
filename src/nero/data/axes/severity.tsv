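harmful	beneficial
serious	benign
life-altering	common
disruptive	undisruptive
dying	recovering
dangerous	safe
threatening	low-priority
high_mortality	harmless
costly	cheap
hospitalized	self-administered
hospital	work
debt	savings
low_quality_of_life	undisruptive
hazard	routine
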