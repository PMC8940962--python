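# Sidecar for the synthetic HAO reference alignment.
anchor_ref: Neuropaea_HAO_synthetic
anchor_pos: 63   # 1-based ungapped position of the key tyrosine in the anchor row
class_labels:
  Neuropaea_HAO_synthetic: AOB-HAO
  Nmobilis_HAO_synthetic: AOB-HAO
  Kstuttgartiensis_HAO_synthetic: anammox-HAO
  Cfecus_eHao_synthetic: epsilonHao
  Ccurvus_eHao_synthetic: epsilonHao
  Cmediatlanticus_eHao_synthetic: epsilonHao
  Nprofundicola_eHao_synthetic: epsilonHao
  NarLike1_synthetic: nitrate-reductase-like
  NarLike2_synthetic: nitrate-reductase-like
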