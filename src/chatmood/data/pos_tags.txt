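# Frozen 46-tag English part-of-speech inventory (Penn-Treebank style), version 1.
# 36 word-level tags followed by 10 punctuation/symbol tags. Order defines vector indexing.
CC
CD
DT
EX
FW
IN
JJ
JJR
JJS
LS
MD
NN
NNS
NNP
NNPS
PDT
POS
PRP
PRP$
RB
RBR
RBS
RP
SYM
TO
UH
VB
VBD
VBG
VBN
VBP
VBZ
WDT
WP
WP$
WRB
.
,
:
``
''
-LRB-
-RRB-
$
#
HYPH
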