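form	lemma
bound	bind
binding	bind
activating	activate
activated	activate
mediating	mediate
mediated	mediate
regulating	regulate
regulated	regulate
encoding	encode
encoded	encode
phosphorylating	phosphorylate
phosphorylated	phosphorylate
associating	associate
associated	associate
inducing	induce
induced	induce
expressing	express
expressed	express
increasing	increase
increased	increase
decreasing	decrease
decreased	decrease
suppressing	suppress
suppressed	suppress
interacting	interact
occurring	occur
occurred	occur
triggering	trigger
triggered	trigger
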