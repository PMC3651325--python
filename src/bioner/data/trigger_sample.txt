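# Synthetic sample trigger-word lexicon: domain terms whose presence near a
# token hints at an entity mention (nouns, verbs, adjectives).
activation
stimulation
expression
phosphorylation
transcription
translation
regulation
inhibition
binding
signaling
induction
overexpression
mutation
deletion
amplification
methylation
pathway
receptor
kinase
ligand
promoter
enhancer
antibody
cytokine
apoptosis
proliferation
differentiation
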