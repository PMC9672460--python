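# Tissue-composition constants for the composition-based partition method
# (fractional extracellular/intracellular water, neutral lipid, neutral
# phospholipid; tissue:plasma albumin ratio; intracellular pH).
# Values are surrogate reference constants assembled from published
# mammalian tissue-composition compilations (Rodgers & Rowland 2006,
# J Pharm Sci 95:1238; Poulin & Theil 2002); rest_of_body and red_marrow
# are generic fill-ins. v1.
tissue_name,f_extracellular_water,f_intracellular_water,f_neutral_lipid,f_neutral_phospholipid,albumin_ratio,intracellular_pH
lung,0.336,0.446,0.022,0.0128,0.212,7.0
heart,0.320,0.456,0.014,0.0111,0.157,7.0
brain,0.162,0.620,0.039,0.0015,0.048,7.0
adipose,0.135,0.017,0.846,0.0016,0.049,7.0
muscle,0.118,0.630,0.010,0.0072,0.064,7.0
skin,0.382,0.291,0.060,0.0044,0.277,7.0
bone,0.100,0.346,0.017,0.0017,0.100,7.0
gut,0.282,0.475,0.038,0.0125,0.158,7.0
spleen,0.207,0.579,0.0077,0.0113,0.097,7.0
liver,0.161,0.573,0.014,0.0240,0.086,7.0
kidney,0.273,0.483,0.012,0.0240,0.130,7.0
reproductive,0.255,0.525,0.0074,0.0105,0.110,7.0
rest_of_body,0.300,0.450,0.020,0.0100,0.100,7.0
red_marrow,0.270,0.450,0.050,0.0050,0.100,7.0
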