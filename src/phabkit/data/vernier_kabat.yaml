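# Vernier-zone framework positions (Kabat numbering), after the classic
# Foote & Winter platform analysis: framework residues that sit beneath the
# CDR loops and modulate their conformation, hence the usual targets for
# back-mutation when a grafted scaffold loses antigen binding.
#
# The table is data, not code: extend or replace it with a project-specific
# set (e.g. the exact back-mutation set of a particular humanization
# campaign) by passing a custom file to load_vernier_set().
heavy: [2, 27, 28, 29, 30, 47, 48, 49, 67, 69, 71, 73, 78, 93, 94, 103]
light: [2, 4, 35, 36, 46, 47, 48, 49, 64, 66, 68, 69, 71, 98]
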