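# Default interaction keyword lexicon: verbs and nouns that commonly signal
# a protein-protein relationship when they occur between or around the two
# entity names.  One lowercase word per line; replace with a domain list
# (e.g. a curated ~600-entry form) for serious corpus work.
interact
interacts
interaction
interactions
interacting
bind
binds
binding
bound
associate
associates
association
complex
complexes
activate
activates
activation
inhibit
inhibits
inhibition
phosphorylate
phosphorylates
phosphorylation
regulate
regulates
regulation
suppresses
stimulates
induces
mediates
modulates
recruits
targets
cleaves
represses
transactivates
receptor
receptors
ligand
substrate
cofactor
dimerizes
has
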