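acute myeloid leukemia	D015470
breast cancer	D001943
prostate cancer	D011471
colorectal cancer	D015179
lung cancer	D008175
ovarian cancer	D010051
pancreatic cancer	D010190
melanoma	D008545
glioblastoma	D005909
chronic myeloid leukemia	D015464
chronic lymphocytic leukemia	D015451
multiple myeloma	D009101
gastric cancer	D013274
hepatocellular carcinoma	D006528
renal cell carcinoma	D002292
bladder cancer	D001749
endometrial cancer	D016889
thyroid cancer	D013964
lymphoma	D008223
myelodysplastic syndrome	D009190
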