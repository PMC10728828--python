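driver,scenario_label,year,value,rel_sd
renewables,planned,2023,0.2,0.02
renewables,planned,2030,0.3,0.03
renewables,planned,2040,0.44,0.05
renewables,planned,2050,0.55,0.06
renewables,below_2C,2023,0.2,0.02
renewables,below_2C,2030,0.38,0.03
renewables,below_2C,2040,0.65,0.05
renewables,below_2C,2050,0.86,0.06
model_complexity,,2023,1.0,0.0
model_complexity,,2033,8.0,0.25
model_complexity,,2043,64.0,0.35
model_complexity,,2052,330.0,0.45
hardware_efficiency,,2023,1.0,0.0
hardware_efficiency,,2033,4.0,0.15
hardware_efficiency,,2043,16.0,0.25
hardware_efficiency,,2052,60.0,0.3
cases,,2023,1.0,0.0
cases,,2030,1.12,0.02
cases,,2040,1.35,0.04
cases,,2052,1.65,0.06
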