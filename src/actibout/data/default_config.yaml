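# Default processing configuration.
#
# Cut points: per-second summed gravity-subtracted SVM thresholds (g·s per
# 1-s epoch) for children's wrist-worn accelerometry.  Derived from the youth
# wrist GENEActiv calibration of Schaefer CA, Nigg CR, Hill JO, Brink LA,
# Browning RC (2014), "Establishing and evaluating wrist cutpoints for the
# GENEActiv accelerometer in youth", Med Sci Sports Exerc 46(4):826-33:
# mean gravity-subtracted SVM of 0.190 g (sedentary/light) and 0.314 g
# (light/MVPA) per second, converted to the summed convention at the 60 Hz
# sampling rate (0.190*60 = 11.40; 0.314*60 = 18.84).
cut_points:
  sedentary_upper_gs: 11.40
  light_upper_gs: 18.84

# Wear-time validity protocol (Mattocks-style): a day needs >=10 h of data,
# is non-wear when >80% of classified daytime (06:00-21:00) epochs are
# sedentary, and a participant needs >=3 valid days.
wear_rules:
  min_hours_per_day: 10
  nonwear_sedentary_fraction: 0.80
  nonwear_window: ["06:00", "21:00"]
  min_valid_days: 3

# Daytime analysis window for epoching/bout features; its complement
# (22:00-07:00) is the sleep-time exclusion for sedentary accumulation.
windows:
  analysis: ["07:00", "22:00"]

sampling_rate_hz: 60
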