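# Demonstration pipeline configuration: a small two-experiment MAGIC study
# with planted QTL (constitutive, treatment-specific and interactive).
seed: 42
simulate:
  map:
    n_markers: 200
    n_chromosomes: 4
    total_cM: 480.0
  founders:
    diversity: 1.0
    n_genes_per_chrom: 25
    n_variants_per_gene_region: 8
  lines:
    n_lines: 100
    n_selfing_generations: 3
    genotyping_error: 0.005
  experiments:
    - name: Exp1
      treatments: [control, WD]
      traits:
        - trait: FW
          transform: log
          mu: 3.5
          target_h2: 0.8
          treatment_offsets: {WD: -0.25}
          qtls:
            # constitutive: expressed in both treatments
            - chrom: chr02
              position_cM: 60.0
              effects: [0.45, 0.45, -0.1, -0.1, -0.1, -0.1, -0.25, -0.25]
            # interactive: effect only under water deficit
            - chrom: chr03
              position_cM: 30.0
              effects: [0.35, -0.05, -0.05, -0.05, -0.05, -0.05, -0.05, -0.05]
              treatment_scale: {control: 0.0, WD: 1.0}
        - trait: SSC
          mu: 6.0
          target_h2: 0.7
          treatment_offsets: {WD: 0.7}
          qtls:
            - chrom: chr01
              position_cM: 40.0
              effects: [0.8, -0.2, 0.6, -0.2, -0.2, -0.2, -0.3, -0.3]
    - name: Exp2
      treatments: [control, SS]
      traits:
        - trait: Leaf
          mu: 30.0
          target_h2: 0.7
          treatment_offsets: {SS: -4.0}
          qtls:
            - chrom: chr04
              position_cM: 80.0
              effects: [2.5, 2.5, 2.5, 2.5, -2.5, -2.5, -2.5, -2.5]
analysis:
  error_rate: 0.005
  grid_step_cM: 2.0
  lod_threshold: 3.0
  max_ci_mb: 20.0
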