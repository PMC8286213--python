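# Proposed Ga-68 specification limits for multi-centre PET-CT trials.
# family "conventional" covers OSEM_5/6.4 and OSEM+TOF_5/6.4; family
# "advanced" covers PSF_5/6.4 and penalised-likelihood BPL_800.
# Bounds are recovery-coefficient type (often quoted as SUV_max /
# SUV_mean / SUV_peak bands; the quantities are per-sphere RCs).
family,metric,diameter_mm,lower,upper
conventional,RC_max,37,0.91,1.14
conventional,RC_mean,37,0.68,0.88
conventional,RC_peak,37,0.85,1.04
conventional,RC_max,28,0.87,1.11
conventional,RC_mean,28,0.63,0.81
conventional,RC_peak,28,0.81,1.00
conventional,RC_max,22,0.78,1.11
conventional,RC_mean,22,0.55,0.78
conventional,RC_peak,22,0.70,0.94
conventional,RC_max,17,0.74,0.93
conventional,RC_mean,17,0.50,0.67
conventional,RC_peak,17,0.58,0.69
conventional,RC_max,13,0.56,0.66
conventional,RC_mean,13,0.37,0.47
conventional,RC_peak,13,0.37,0.45
conventional,RC_max,10,0.32,0.49
conventional,RC_mean,10,0.20,0.34
conventional,RC_peak,10,0.21,0.31
advanced,RC_max,37,0.92,1.14
advanced,RC_mean,37,0.71,0.89
advanced,RC_peak,37,0.83,1.06
advanced,RC_max,28,0.90,1.17
advanced,RC_mean,28,0.65,0.88
advanced,RC_peak,28,0.83,1.07
advanced,RC_max,22,0.87,1.19
advanced,RC_mean,22,0.58,0.85
advanced,RC_peak,22,0.76,1.04
advanced,RC_max,17,0.84,1.16
advanced,RC_mean,17,0.51,0.79
advanced,RC_peak,17,0.62,0.84
advanced,RC_max,13,0.65,0.99
advanced,RC_mean,13,0.37,0.63
advanced,RC_peak,13,0.39,0.56
advanced,RC_max,10,0.41,0.59
advanced,RC_mean,10,0.25,0.34
advanced,RC_peak,10,0.24,0.34
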