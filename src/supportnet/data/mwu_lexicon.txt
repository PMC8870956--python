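# Default multi-word-unit lexicon: domain phrases treated as single nodes
# (underscore-joined). Longest match, left to right. Override with a plain
# text file, one phrase per line.
side effects
side effect
pancreatic cancer
breast cancer
lung cancer
colon cancer
skin cancer
prostate cancer
ovarian cancer
renal cell cancer
basal cell
health care
healthy diet
pain symptoms
fatty tissue
chest cavity
medical insurance
radiation therapy
bone marrow
blood test
blood pressure
support group
family member
family members
daily life
birthday wishes
holiday plans
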