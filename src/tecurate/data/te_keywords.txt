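# Vocabulary of TE-related terms, one phrase per line.
# Matching is case-insensitive on word boundaries; '#' starts a comment.
# Extend freely: descriptions matching any phrase mark evidence as TE-related.
reverse transcriptase
retrotranscriptase
ribonuclease H
RNase H
integrase
aspartyl protease
gag
pol
gag-pol
transposase
apurinic endonuclease
AP endonuclease
apurinic
Gypsy
Ty3
LINE
R2
SINE
retrotransposon
retroelement
retrovirus
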