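# 15-node sample network for the step-by-step scoring walkthrough.
# Reconstructed by constraint search from the published per-node
# degree, shell, similarity and influence values; see glinet.fixtures.
v1 v2
v1 v3
v1 v4
v1 v5
v1 v6
v1 v8
v2 v3
v2 v4
v2 v8
v2 v9
v3 v4
v3 v15
v4 v13
v4 v14
v5 v6
v5 v7
v8 v9
v8 v10
v8 v11
v10 v12
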