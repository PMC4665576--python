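# Pre-test probability of coronary artery disease by presenting symptom,
# as diseased/total counts from prior studies.
- {label: nonanginal chest pain, k: 146, m: 913}
- {label: atypical angina, k: 963, m: 1931}
- {label: typical angina, k: 1874, m: 2108}
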