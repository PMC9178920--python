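network,site,borough,zcta_id,observed,modeled
AQS,JHS 126,Brooklyn,11222,7.87,7.99
AQS,PS 274,Brooklyn,11221,6.42,6.69
AQS,PS 314,Brooklyn,11220,6.42,7.90
AQS,CCNY,Manhattan,10031,8.14,10.17
AQS,Division Street,Manhattan,10038,8.01,10.58
AQS,Intermediate School 143,Manhattan,10033,8.50,11.26
AQS,IS 45,Manhattan,10035,7.32,9.34
AQS,PS 19,Manhattan,10009,8.23,11.54
AQS,Freshkills West,Staten island,10314,7.33,6.37
AQS,Richmond Post Office,Staten island,10302,6.76,6.80
AQS,IS 52,Bronx,10459,6.13,7.86
AQS,IS 74,Bronx,10474,7.12,7.14
AQS,Morrisania,Bronx,10452,6.62,10.05
AQS,Pfizer Lab Site,Bronx,10467,8.19,8.67
AQS,Maspeth Library,Queens,11378,6.46,6.18
AQS,Queens College 2,Queens,11367,6.60,5.89
NYCCAS,Staten Island,Richmond,10306,6.12,6.33
NYCCAS,Queens,Queens,11367,6.59,5.52
NYCCAS,New York,New York,10026,6.77,10.89
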