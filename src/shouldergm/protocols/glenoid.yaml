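# Glenoid cavity protocol: 5 type-II landmarks (4 margin curvature maxima
# plus the craniocaudal curvature point at the centre of the articular
# surface) and 8 semilandmarks - 4 on the margin outline between landmark
# pairs and 4 across the surface towards the centre.  Semilandmarks are
# not slid by default; set slide_by_default or the CLI --slide flag to
# enable sliding.
name: glenoid
slide_by_default: false
landmarks:
  - [L1, II]   # maximum curvature, proximal aspect of margin
  - [L2, II]   # maximum curvature, distal aspect
  - [L3, II]   # maximum curvature, anterior aspect
  - [L4, II]   # maximum curvature, posterior aspect
  - [L5, II]   # maximum craniocaudal curvature, centre of articular surface
  - [SL1, SL]  # margin midpoint L1-L3
  - [SL2, SL]  # margin midpoint L3-L2
  - [SL3, SL]  # margin midpoint L2-L4
  - [SL4, SL]  # margin midpoint L4-L1
  - [SL5, SL]  # surface midpoint L1-L5
  - [SL6, SL]  # surface midpoint L2-L5
  - [SL7, SL]  # surface midpoint L3-L5
  - [SL8, SL]  # surface midpoint L4-L5
curves:
  - [L1, SL1, L3]
  - [L3, SL2, L2]
  - [L2, SL3, L4]
  - [L4, SL4, L1]
  - [L1, SL5, L5]
  - [L2, SL6, L5]
  - [L3, SL7, L5]
  - [L4, SL8, L5]
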