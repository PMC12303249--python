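# Default keyword lexicon for snippet extraction.
# One case-insensitive phrase (1-5 words) per line; '#' starts a comment.
# Substitute your own list via --lexicon / RunConfig.lexicon_path.
genetic testing
germline
genetic counseling
BRCA
BRCA1
BRCA2
PALB2
CHEK2
ATM
TP53
CDH1
STK11
PTEN
pathogenic variant
hereditary breast
genomic medicine service
clinical cancer genetics
gene panel
Myriad
Invitae
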