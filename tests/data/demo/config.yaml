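# Seeded demo pipeline: two chemicals (one PFAS, one PAH), three doses each,
# both sexes, latent log2 mode, planted PPARa / HNF4a / AHR regulon effects.
seed: 20240605
output_dir: demo_out
inputs:
  regulons: regulons.tsv
  mie_list: mies.tsv
  mapping: mapping.tsv
  signature: signature.tsv
simulate:
  n_genes: 40
  n_treated: 3
  n_control: 4
  noise_sd: 0.4
  mode: lognormal
  chemicals:
    - {name: "6:1 FTOH", class: PFAS, doses: [12, 111, 1000]}
    - {name: "2,3-Benzofluorene", class: PAH, doses: [12, 111, 1000]}
  effects:
    - {tf: Ppara, direction: up, max_log2fc: 2.0, classes: [PFAS]}
    - {tf: Hnf4a, direction: down, max_log2fc: 1.5, sex_directions: {female: up, male: down}}
    - {tf: Ahr, direction: up, max_log2fc: 1.5, class_directions: {PAH: up, PFAS: down}}
thresholds:
  up: 0.6
  down: -0.6
  q: 0.1
  trend_window: 3
  min_support: 1.0
  min_median_corr: 0.8
  top_doses: 3
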