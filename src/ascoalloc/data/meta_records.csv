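# Published regional means of annual reproductive allocation (annRA, fraction)
# and reproduction-peak month for Ascophyllum nodosum across its range.
# latitude_degN: decimal degrees N. sst_mean_C left blank (site covariate input).
# The new-england source reports reproductive effort only (re-only tag): its
# value is RE, not annRA, and is excluded from the annRA regressions.
region_id,latitude_degN,sst_mean_C,annRA,peak_month,peak_jd,source
portugal,42.00,,0.76,11,,araujo2022
new_england,43.00,,0.53,,,mathieson-guo re-only
maine,45.00,,0.61,,,vadas1995
nova_scotia,44.00,,0.56,,,cousens1986
france,48.00,,0.54,2,,araujo2022
sweden,58.50,,0.53,,,aberg1996
hirsholmene,57.75,,0.51,4,,this-study
kobbefjord,64.233,,0.50,7,,this-study
kronprinsen,69.033,,0.33,8,,this-study
qeqertarsuaq,69.400,,0.39,8,,this-study
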