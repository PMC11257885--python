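# Dexamethasone compound parameters — literature defaults.
# The original platform compound file is not public; these values are
# assembled from published human PK and physicochemical data and every
# field can be overridden from a user-supplied YAML.
name: dexamethasone
molecular_weight: 392.46        # g/mol
fu_adult: 0.30                  # unbound fraction in adult plasma
blood_plasma_ratio: 0.93
clint_u_adult_ul_min_mg: 7.5    # unbound CLint, uL/min/mg microsomal protein
fm_cyp3a4: 0.85                 # fraction of hepatic CLint via CYP3A4
renal_fraction: 0.5             # fraction of unbound GFR realized as CLrenal
kp_liver: 1.2                   # tissue:plasma partition coefficients
kp_kidney: 1.2
kp_rest: 0.9
default_infusion_duration_h: 0.1
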