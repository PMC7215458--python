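variable,code,label,count
period,1,early_morning,226
period,2,forenoon,128
period,3,afternoon,145
period,4,evening,70
hazmat_class,1,explosives,12
hazmat_class,2,gases,108
hazmat_class,3,flammable_liquids,317
hazmat_class,4,flammable_solids,11
hazmat_class,5,oxidizers_organic_peroxides,3
hazmat_class,6,toxic_infectious,34
hazmat_class,7,radioactive,0
hazmat_class,8,corrosives,84
hazmat_class,9,miscellaneous,0
accident_type,1,collision,352
accident_type,2,non_collision,217
specific_type,1,collision_fixed_object,18
specific_type,2,collision_non_motor_vehicle,6
specific_type,3,collision_parked_vehicle,12
specific_type,4,two_vehicle_head_on,60
specific_type,5,two_vehicle_sideswipe,16
specific_type,6,two_vehicle_rear_end,179
specific_type,7,multivehicle_collision,57
specific_type,8,rollover,135
specific_type,9,run_off_road,49
specific_type,10,tank_accessory_failure,8
specific_type,11,vehicle_defect,17
specific_type,12,other,12
cause_factor,1,environment,50
cause_factor,2,management_failure,42
cause_factor,3,equipment_malfunction,44
cause_factor,4,driver_error,433
severity_level,1,II,408
severity_level,2,III,104
severity_level,3,IV,32
severity_level,4,V,25
road_level,1,highway_high_level,493
road_level,2,urban_road,37
road_level,3,rural_road,39
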