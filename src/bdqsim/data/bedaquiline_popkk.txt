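# Bedaquiline population-PK parameter file (reconstructed / synthetic)
#
# Structural model: dual-path first-order oral absorption into a linear
# 4-compartment disposition system (central + 3 peripheral), first-order
# elimination from the central compartment.  All disposition parameters are
# apparent (scaled by the reference bioavailability); F is a relative
# bioavailability with reference value 1.
#
# Provenance: the structure, the covariate multipliers and the set of
# between-subject variance terms follow the published population model for
# bedaquiline; the numeric magnitudes in this file are a reconstruction
# calibrated once to well-established bedaquiline pharmacokinetic
# characteristics (apparent clearance ~2.6 L/h in MDR-TB patients, tmax
# ~4-6 h, terminal half-life ~5.5 months, ~2.4x peak accumulation over the
# 14-day 400 mg QD loading phase).  They are not a verbatim transcription.
#
# format: key  value  unit  # comment
cl_typical          2.6     L/h     # apparent clearance, reference: nonblack male MDR-TB
vc_typical          164.0   L       # apparent central volume, reference: male
vp1                 400.0   L       # shallow peripheral volume
vp2                 2400.0  L       # intermediate peripheral volume
vp3                 6000.0  L       # deep peripheral volume (terminal phase)
q1                  15.0    L/h     # intercompartmental clearance, central<->shallow
q2                  5.0     L/h     # intercompartmental clearance, central<->intermediate
q3                  2.2     L/h     # intercompartmental clearance, central<->deep
ka_path1            0.35    1/h     # absorption rate, fast pathway
ka_path2            0.12    1/h     # absorption rate, slow pathway
lag_path1           0.0     h       # absorption lag, fast pathway
lag_path2           1.5     h       # absorption lag, slow pathway
f_typical           1.0     -       # relative oral bioavailability, reference: MDR-TB
fr_path1_typical    0.6     -       # fraction of absorbed dose via fast pathway
omega2_cl           0.15    -       # BSV variance, log clearance
omega2_vc           0.10    -       # BSV variance, log central volume
omega2_f            0.10    -       # BSV variance, log bioavailability
omega2_fr           0.50    -       # BSV variance, logit path-1 fraction
sigma_prop          0.30    -       # proportional residual error (CV)
sigma_add           0.0     ug/mL   # additive residual error (SD)
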