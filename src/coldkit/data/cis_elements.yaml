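# Starter cis-element dictionary: canonical consensus strings for 30 common
# plant promoter elements, each assigned to one of five functional classes.
# Database motif definitions are versioned; edit or replace this file to match
# the dictionary your study used.
ABRE:            {pattern: ACGTG,       class: hormone}     # ABA response
ABRE3a:          {pattern: TACGTG,      class: hormone}
ABRE4:           {pattern: CACGTA,      class: hormone}
CGTCA-motif:     {pattern: CGTCA,       class: hormone}     # MeJA response
TGACG-motif:     {pattern: TGACG,       class: hormone}     # MeJA response
TCA-element:     {pattern: CCATCTTTTT,  class: hormone}     # salicylic acid
TGA-element:     {pattern: AACGAC,      class: hormone}     # auxin
AuxRR-core:      {pattern: GGTCCAT,     class: hormone}     # auxin
P-box:           {pattern: CCTTTTG,     class: hormone}     # gibberellin
GARE-motif:      {pattern: TCTGTTG,     class: hormone}     # gibberellin
ARE:             {pattern: AAACCA,      class: stress}      # anaerobic induction
MBS:             {pattern: CAACTG,      class: stress}      # MYB drought site
LTR:             {pattern: CCGAAA,      class: stress}      # low temperature
TC-rich_repeats: {pattern: ATTTTCTTCA,  class: stress}      # defense/stress
WUN-motif:       {pattern: AAATTTCCT,   class: stress}      # wounding
DRE-core:        {pattern: GCCGAC,      class: stress}      # dehydration
W-box:           {pattern: TTGACC,      class: stress}      # WRKY defense
G-box:           {pattern: CACGTG,      class: light}
Box-4:           {pattern: ATTAAT,      class: light}
GT1-motif:       {pattern: GGTTAA,      class: light}
TCT-motif:       {pattern: TCTTAC,      class: light}
MRE:             {pattern: AACCTAA,     class: light}
I-box:           {pattern: GATAAGRTT,   class: light}
CAT-box:         {pattern: GCCACT,      class: development} # meristem
O2-site:         {pattern: GATGAYRTGR,  class: development} # zein metabolism
GCN4-motif:      {pattern: TGAGTCA,     class: development} # endosperm
circadian:       {pattern: CAANNNNATC,  class: development}
RY-element:      {pattern: CATGCATG,    class: development} # seed-specific
CAAT-box:        {pattern: CCAAT,       class: other}       # core promoter
TATA-box:        {pattern: TATAWAW,     class: other}       # core promoter
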