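domain,code,category
water,piped into dwelling,improved
water,piped to yard plot,improved
water,public tap standpipe,improved
water,tube well borehole,improved
water,protected dug well,improved
water,protected spring,improved
water,rainwater,improved
water,bottled water,improved
water,unprotected dug well,unimproved
water,unprotected spring,unimproved
water,tanker truck,unimproved
water,cart with small tank,unimproved
water,surface water,unimproved
sanitation,flush to piped sewer,improved
sanitation,flush to septic tank,improved
sanitation,flush to pit latrine,improved
sanitation,ventilated improved pit latrine,improved
sanitation,pit latrine with slab,improved
sanitation,composting toilet,improved
sanitation,flush to elsewhere,unimproved
sanitation,pit latrine without slab,unimproved
sanitation,bucket toilet,unimproved
sanitation,hanging toilet,unimproved
sanitation,open defecation,unimproved
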