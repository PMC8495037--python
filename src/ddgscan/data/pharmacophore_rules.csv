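# Pharmacophore atom-typing rules, version ddgscan-rules-v1.
# Schema: residue,atom,classes  (classes separated by '|').
# residue '*' is a wildcard matched when no residue-specific row exists.
# Every label decision for a protein heavy atom is traceable to one row here;
# atoms with no matching row degrade to Neutral with a logged warning.
residue,atom,classes
*,N,HDonor
*,CA,Neutral
*,C,Neutral
*,O,HAcceptor
*,OXT,Negative|HAcceptor
PRO,N,Neutral
ALA,CB,Hydrophobic
ARG,CB,Hydrophobic
ARG,CG,Hydrophobic
ARG,CD,Neutral
ARG,NE,Positive|HDonor
ARG,CZ,Neutral
ARG,NH1,Positive|HDonor
ARG,NH2,Positive|HDonor
ASN,CB,Hydrophobic
ASN,CG,Neutral
ASN,OD1,HAcceptor
ASN,ND2,HDonor
ASP,CB,Hydrophobic
ASP,CG,Neutral
ASP,OD1,Negative|HAcceptor
ASP,OD2,Negative|HAcceptor
CYS,CB,Hydrophobic
CYS,SG,Hydrophobic
GLN,CB,Hydrophobic
GLN,CG,Hydrophobic
GLN,CD,Neutral
GLN,OE1,HAcceptor
GLN,NE2,HDonor
GLU,CB,Hydrophobic
GLU,CG,Hydrophobic
GLU,CD,Neutral
GLU,OE1,Negative|HAcceptor
GLU,OE2,Negative|HAcceptor
HIS,CB,Hydrophobic
HIS,CG,Aromatic
HIS,ND1,Positive|Aromatic|HDonor
HIS,CD2,Aromatic
HIS,CE1,Aromatic
HIS,NE2,Positive|Aromatic|HDonor
ILE,CB,Hydrophobic
ILE,CG1,Hydrophobic
ILE,CG2,Hydrophobic
ILE,CD1,Hydrophobic
LEU,CB,Hydrophobic
LEU,CG,Hydrophobic
LEU,CD1,Hydrophobic
LEU,CD2,Hydrophobic
LYS,CB,Hydrophobic
LYS,CG,Hydrophobic
LYS,CD,Hydrophobic
LYS,CE,Neutral
LYS,NZ,Positive|HDonor
MET,CB,Hydrophobic
MET,CG,Hydrophobic
MET,SD,Hydrophobic
MET,CE,Hydrophobic
PHE,CB,Hydrophobic
PHE,CG,Aromatic|Hydrophobic
PHE,CD1,Aromatic|Hydrophobic
PHE,CD2,Aromatic|Hydrophobic
PHE,CE1,Aromatic|Hydrophobic
PHE,CE2,Aromatic|Hydrophobic
PHE,CZ,Aromatic|Hydrophobic
PRO,CB,Hydrophobic
PRO,CG,Hydrophobic
PRO,CD,Neutral
SER,CB,Neutral
SER,OG,HDonor|HAcceptor
THR,CB,Neutral
THR,OG1,HDonor|HAcceptor
THR,CG2,Hydrophobic
TRP,CB,Hydrophobic
TRP,CG,Aromatic|Hydrophobic
TRP,CD1,Aromatic
TRP,CD2,Aromatic|Hydrophobic
TRP,NE1,Aromatic|HDonor
TRP,CE2,Aromatic
TRP,CE3,Aromatic|Hydrophobic
TRP,CZ2,Aromatic|Hydrophobic
TRP,CZ3,Aromatic|Hydrophobic
TRP,CH2,Aromatic|Hydrophobic
TYR,CB,Hydrophobic
TYR,CG,Aromatic|Hydrophobic
TYR,CD1,Aromatic|Hydrophobic
TYR,CD2,Aromatic|Hydrophobic
TYR,CE1,Aromatic|Hydrophobic
TYR,CE2,Aromatic|Hydrophobic
TYR,CZ,Aromatic
TYR,OH,HDonor|HAcceptor
VAL,CB,Hydrophobic
VAL,CG1,Hydrophobic
VAL,CG2,Hydrophobic
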