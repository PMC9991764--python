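equation_id,sex,term,coefficient,unit,provenance
kawasaki,any,scale,16.3,mmol/day,"Kawasaki et al. 1993, Clin Exp Pharmacol Physiol 20:7-14"
kawasaki,any,exponent,0.5,dimensionless,"Kawasaki et al. 1993"
kawasaki,M,prcr_intercept,-79.9,mg/day,"Kawasaki et al. 1993 (predicted 24-h creatinine, men)"
kawasaki,M,prcr_age,-12.63,mg/day per year,"Kawasaki et al. 1993"
kawasaki,M,prcr_weight,15.12,mg/day per kg,"Kawasaki et al. 1993"
kawasaki,M,prcr_height,7.39,mg/day per cm,"Kawasaki et al. 1993"
kawasaki,F,prcr_intercept,-74.5,mg/day,"Kawasaki et al. 1993 (predicted 24-h creatinine, women)"
kawasaki,F,prcr_age,-4.72,mg/day per year,"Kawasaki et al. 1993"
kawasaki,F,prcr_weight,8.58,mg/day per kg,"Kawasaki et al. 1993"
kawasaki,F,prcr_height,5.09,mg/day per cm,"Kawasaki et al. 1993"
tanaka,any,scale,21.98,mmol/day,"Tanaka et al. 2002, J Hum Hypertens 16:97-103"
tanaka,any,exponent,0.392,dimensionless,"Tanaka et al. 2002"
tanaka,any,prcr_intercept,-2244.45,mg/day,"Tanaka et al. 2002 (predicted 24-h creatinine, both sexes)"
tanaka,any,prcr_age,-2.04,mg/day per year,"Tanaka et al. 2002"
tanaka,any,prcr_weight,14.89,mg/day per kg,"Tanaka et al. 2002"
tanaka,any,prcr_height,16.14,mg/day per cm,"Tanaka et al. 2002"
intersalt_with_k,M,intercept,25.46,mmol/day,"Brown et al. 2013, Am J Epidemiol 177:1180-92 (INTERSALT with K, men)"
intersalt_with_k,M,spot_na,0.46,mmol/day per mmol/L,"Brown et al. 2013"
intersalt_with_k,M,spot_k,-0.13,mmol/day per mmol/L,"Brown et al. 2013"
intersalt_with_k,M,spot_creat_mmol,-2.75,mmol/day per mmol/L,"Brown et al. 2013"
intersalt_with_k,M,bmi,4.10,mmol/day per kg/m2,"Brown et al. 2013"
intersalt_with_k,M,age,0.26,mmol/day per year,"Brown et al. 2013"
intersalt_with_k,F,intercept,5.07,mmol/day,"Brown et al. 2013 (INTERSALT with K, women)"
intersalt_with_k,F,spot_na,0.34,mmol/day per mmol/L,"Brown et al. 2013"
intersalt_with_k,F,spot_k,-0.09,mmol/day per mmol/L,"Brown et al. 2013"
intersalt_with_k,F,spot_creat_mmol,-2.16,mmol/day per mmol/L,"Brown et al. 2013"
intersalt_with_k,F,bmi,2.39,mmol/day per kg/m2,"Brown et al. 2013"
intersalt_with_k,F,age,2.35,mmol/day per year,"Brown et al. 2013"
intersalt_with_k,F,age2,-0.03,mmol/day per year^2,"Brown et al. 2013"
intersalt_without_k,M,intercept,23.51,mmol/day,"Brown et al. 2013 (INTERSALT without K, men)"
intersalt_without_k,M,spot_na,0.45,mmol/day per mmol/L,"Brown et al. 2013"
intersalt_without_k,M,spot_creat_mmol,-3.09,mmol/day per mmol/L,"Brown et al. 2013"
intersalt_without_k,M,bmi,4.16,mmol/day per kg/m2,"Brown et al. 2013"
intersalt_without_k,M,age,0.22,mmol/day per year,"Brown et al. 2013"
intersalt_without_k,F,intercept,3.74,mmol/day,"Brown et al. 2013 (INTERSALT without K, women)"
intersalt_without_k,F,spot_na,0.33,mmol/day per mmol/L,"Brown et al. 2013"
intersalt_without_k,F,spot_creat_mmol,-2.44,mmol/day per mmol/L,"Brown et al. 2013"
intersalt_without_k,F,bmi,2.42,mmol/day per kg/m2,"Brown et al. 2013"
intersalt_without_k,F,age,2.34,mmol/day per year,"Brown et al. 2013"
intersalt_without_k,F,age2,-0.03,mmol/day per year^2,"Brown et al. 2013"
mage,any,scale,1.0,mmol/day,"ratio method: spot Na / spot creatinine x predicted 24-h creatinine"
mage,any,exponent,1.0,dimensionless,"ratio method"
mage,M,prcr_w15sqrth,0.21,mg/day per kg^1.5 cm^0.5,"reconstructed: body-size creatinine model calibrated to ~1600 mg/d at 70 kg / 170 cm (men); source coefficients unavailable"
mage,F,prcr_w15sqrth,0.18,mg/day per kg^1.5 cm^0.5,"reconstructed: calibrated to ~1060 mg/d at 60 kg / 160 cm (women); source coefficients unavailable"
toft,any,scale,1.0,mmol/day,"ratio method: spot Na / spot creatinine x predicted 24-h creatinine"
toft,any,exponent,1.0,dimensionless,"ratio method"
toft,M,prcr_per_kg,24.0,mg/day per kg,"reconstructed: mid-range normal male creatinine excretion 14.4-33.6 mg/kg/d; source coefficients unavailable"
toft,F,prcr_per_kg,18.0,mg/day per kg,"reconstructed: mid-range normal female creatinine excretion 10.8-25.2 mg/kg/d; source coefficients unavailable"
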