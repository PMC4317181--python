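# Proximal humerus protocol: 21 type-II landmarks (tubercle insertion
# facets L1-L16, articular perimeter L17-L21) plus 4 semilandmarks on the
# articular arc, each anchored between perimeter landmarks.  The
# semilandmarks slide by default (Procrustes-distance criterion).
name: humerus
slide_by_default: true
landmarks:
  - [L1, II]   # distal end, subscapularis insertion (minor tubercle)
  - [L2, II]   # proximal end, subscapularis insertion
  - [L3, II]   # lateral point, subscapularis insertion
  - [L4, II]   # medial point, subscapularis insertion
  - [L5, II]   # anterior end, supraspinatus insertion (major tubercle)
  - [L6, II]   # posterior end, supraspinatus insertion
  - [L7, II]   # lateral point, supraspinatus insertion
  - [L8, II]   # medial point, supraspinatus insertion
  - [L9, II]   # distal end, infraspinatus insertion
  - [L10, II]  # proximal end, infraspinatus insertion
  - [L11, II]  # lateral point, infraspinatus insertion
  - [L12, II]  # medial point, infraspinatus insertion
  - [L13, II]  # distal end, teres minor insertion
  - [L14, II]  # proximal end, teres minor insertion
  - [L15, II]  # lateral point, teres minor insertion
  - [L16, II]  # medial point, teres minor insertion
  - [L17, II]  # articular perimeter / major tubercle intersection (post./ant. view)
  - [L18, II]  # maximum curvature of articular perimeter (ML-AP plane)
  - [L19, II]  # most medial point of articular perimeter
  - [L20, II]  # perimeter / minor tubercle intersection (superior view)
  - [L21, II]  # perimeter / major tubercle intersection (superior view)
  - [SL1, SL]  # midpoint L17-L18 on articular surface
  - [SL2, SL]  # midpoint L18-L19 on articular surface
  - [SL3, SL]  # midpoint L20-L18 on articular surface
  - [SL4, SL]  # midpoint L21-L18 on articular surface
curves:
  - [L17, SL1, L18]
  - [L18, SL2, L19]
  - [L20, SL3, L18]
  - [L21, SL4, L18]
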