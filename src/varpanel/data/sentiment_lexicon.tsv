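associated	0.4
association	0.4
increased	0.3
increases	0.3
increase	0.25
risk	-0.2
significant	0.3
significantly	0.3
correlated	0.35
correlation	0.35
linked	0.3
link	0.25
causes	0.4
caused	0.4
causal	0.4
contributes	0.3
contributing	0.3
predisposes	0.35
predisposition	0.35
pathogenic	0.4
deleterious	0.3
susceptibility	0.3
responsible	0.3
implicated	0.35
involved	0.3
confers	0.3
driver	0.35
oncogenic	0.4
elevated	0.25
higher	0.2
predicts	0.3
predictive	0.3
prognostic	0.3
benign	-0.3
neutral	-0.2
unrelated	-0.4
absent	-0.3
lacked	-0.3
failed	-0.35
insignificant	-0.35
weak	-0.2
unlikely	-0.3
protective	-0.1
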