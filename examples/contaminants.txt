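# Contaminant classes commonly flagged in affinity-purification/MS.
# Edit freely: '[category]' headers, one glob pattern per line.

[heat_shock]
Hsp*
Hsc7*

[ribosomal]
RpL*
RpS*
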