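{
  "tvcl": 7.56,
  "tvv1": 85.6,
  "tvq": 1.3,
  "tvv2": 286.0,
  "hill": 3.4,
  "tm50": 47.7,
  "theta_scr": 0.0188,
  "omega_cl": 0.221,
  "omega_v1": 0.329,
  "omega_iov_cl": 0.187,
  "sigma_prop": 0.233
}
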