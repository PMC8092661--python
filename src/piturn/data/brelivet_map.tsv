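# Generic alignment position (1-based) <-> Brelivet marker numbering.
# Marker positions 5, 55 and 90 have no anchored alignment column in the
# packaged table; audits skip them unless the user supplies a mapping.
# alignment_position	brelivet_position
109	40
111	42
220	50
262	61
263	62
309	93
316	100
321	105
322	106
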