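# Final total-piperacillin population PK model.
# Typical values referenced to 70 kg; fixed allometric scaling (0.75 on CL/Q,
# 1 on V1/V2) plus a power effect of creatinine clearance on CL centered at
# 120 mL/min/1.73 m^2.  Variances are on the log scale: omega2 = (CV)^2 with
# CV as a fraction (28.7% -> 0.287^2).
theta:
  cl: 7.1     # L/h per 70 kg
  v1: 17.2    # L per 70 kg
  q: 3.25     # L/h per 70 kg
  v2: 4.79    # L per 70 kg
covariate_effects:
  - allometric
  - parameter: cl
    covariate: crcl
    kind: power-continuous
    exponent_or_factor: 0.484
    center: 120.0
random:
  omega2:
    cl: 0.082369      # IIV CL, CV 28.7%
    v1: 0.1681        # IIV V1, CV 41%
  pi2:
    pre: 0.142129     # IOV pre-operative, CV 37.7%
    post: 0.112225    # IOV post-operative, CV 33.5%
  sigma2_prop: 0.137641   # proportional residual, CV 37.1%
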