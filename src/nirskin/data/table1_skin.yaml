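# Seven-layer skin model under a glass probe window.
# Thicknesses in cm; C_B / C_H2O are blood and interstitial-water volume
# fractions; mu_s_prime_ref_cm1 is the reduced scattering at 1000 nm with
# mu_s'(lambda) = ref * (lambda/1000 nm)^-exponent.
# Anisotropy g and refractive index n are standard skin-optics defaults.
superstrate:
  n: 1.4
  thickness_cm: 0.02
ambient_n: 1.0
layers:
  - name: stratum_corneum
    kind: stratum_corneum
    thickness_cm: 0.002
    C_B: 0.0
    C_H2O: 0.05
    mu_s_prime_ref_cm1: 45.0
    mu_s_prime_exponent: 1.4
    g: 0.9
    n: 1.37
  - name: living_epidermis
    kind: living_epidermis
    thickness_cm: 0.008
    C_B: 0.0
    C_H2O: 0.20
    mu_s_prime_ref_cm1: 40.0
    mu_s_prime_exponent: 1.3
    g: 0.9
    n: 1.37
  - name: papillary_dermis
    kind: dermal
    thickness_cm: 0.02
    C_B: 0.04
    C_H2O: 0.50
    mu_s_prime_ref_cm1: 30.0
    mu_s_prime_exponent: 1.2
    g: 0.9
    n: 1.37
  - name: upper_blood_net_dermis
    kind: dermal
    thickness_cm: 0.01
    C_B: 0.30
    C_H2O: 0.60
    mu_s_prime_ref_cm1: 22.0
    mu_s_prime_exponent: 1.6
    g: 0.9
    n: 1.37
  - name: reticular_dermis
    kind: dermal
    thickness_cm: 0.16
    C_B: 0.04
    C_H2O: 0.70
    mu_s_prime_ref_cm1: 18.0
    mu_s_prime_exponent: 1.1
    g: 0.9
    n: 1.37
  - name: deep_blood_net_dermis
    kind: dermal
    thickness_cm: 0.012
    C_B: 0.10
    C_H2O: 0.70
    mu_s_prime_ref_cm1: 16.0
    mu_s_prime_exponent: 1.6
    g: 0.9
    n: 1.37
  - name: subcutaneous_tissue
    kind: subcutaneous
    thickness_cm: 0.65
    C_B: 0.05
    C_H2O: 0.70
    mu_s_prime_ref_cm1: 13.0
    mu_s_prime_exponent: 0.9
    g: 0.9
    n: 1.37
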