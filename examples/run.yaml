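# Default main-text parameters: 16 agents, 100 skill types, radius 6,
# complete network, equal mix of copying and collaboration.
n: 16
s: 100
r: 6
width: 100
height: 100
landscape_kind: complex
network: {kind: complete}
schedule: {kind: constant_p, p: 0.5}
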