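# Published Monte Carlo estimates of deaths in the 4 years after job loss
# among displaced EU processed-meat workers, by cause and employment-loss
# scenario (workforce 1,000,000 x 54.2% processed share). Calibration input.
cause,loss_fraction,expected_deaths,ci_low,ci_high
all-cause,0.001,27.23,16.55,37.80
all-cause,0.003,81.69,49.66,113.41
all-cause,0.006,163.38,99.32,226.81
all-cause,0.01,272.30,165.53,378.02
malignant neoplasm,0.001,9.55,-1.12,20.13
malignant neoplasm,0.003,28.66,-3.37,60.38
malignant neoplasm,0.006,57.32,-6.74,120.75
malignant neoplasm,0.01,95.53,-11.24,201.25
circulatory,0.001,8.76,-1.92,19.33
circulatory,0.003,26.28,-5.75,58.00
circulatory,0.006,52.56,-11.51,115.99
circulatory,0.01,87.60,-19.18,193.32
suicide,0.001,2.14,-9.19,12.06
suicide,0.003,6.41,-27.56,36.19
suicide,0.006,12.81,-55.12,72.38
suicide,0.01,21.35,-91.86,120.63
alcohol-related,0.001,1.49,-8.54,12.71
alcohol-related,0.003,4.47,-25.63,38.12
alcohol-related,0.006,8.95,-51.25,76.24
alcohol-related,0.01,14.91,-85.42,127.07
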