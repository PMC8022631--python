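# Default sitting-posture ontology.
#
# Three top-level branches; "sitting straight" is simultaneously the straight
# branch and its own leaf (one shared node), which is what makes the flattened
# encoding exactly 8 units wide for 6 leaves.  The `branch` key gives the
# label used when the node is reported as a root branch.
roots:
  - name: sitting straight
    branch: straight posture
  - name: forward posture
    children:
      - name: lightly hunched
      - name: hunched over
      - name: extremely hunched
  - name: backward posture
    children:
      - name: partially lying
      - name: lying down
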