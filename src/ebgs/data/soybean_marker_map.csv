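marker_id,marker_name,position_cm,linkage_group
M1,Satt005,0.00,1
M74,Satt579,149.39,1
M37,Satt290,241.33,1
M70,Satt537,586.72,1
M4,Satt032,0.00,2
M58,Satt436,196.10,2
M79,Satt605,272.50,2
M69,Satt532,388.23,2
M75,Satt584,0.00,3
M31,Satt234,152.25,3
M49,Satt387,244.95,3
M3,Satt022,304.72,3
M32,Satt247,0.00,4
M43,Satt337,345.39,4
M13,Satt137,439.85,4
M62,Satt475,545.69,4
M47,Satt375,545.69,4
M33,Satt264,609.52,4
M5,Satt046,670.69,4
M34,Satt268,0.00,5
M28,Satt213,345.39,5
M78,Satt602,434.04,5
M52,Satt411,528.24,5
M48,Satt384,600.86,5
M30,Satt231,674.74,5
M77,Satt598,743.69,5
M40,Satt307,0.00,6
M36,Satt286,41.97,6
M53,Satt422,88.51,6
M35,Satt281,164.63,6
M66,Satt520,252.18,6
M80,GMA,300.27,6
M7,Satt082,0.00,7
M50,Satt397,345.39,7
M21,Satt168,0.00,8
M60,Satt467,67.12,8
M10,Satt122,247.35,8
M45,Satt373,0.00,9
M64,Satt495,345.39,9
M20,Satt166,462.25,9
M11,Satt123,0.00,10
M73,Satt576,70.86,10
M9,Satt094,138.02,10
M6,Satt052,0.00,11
M44,Satt353,89.85,11
M61,Satt469,169.72,11
M23,Satt181,169.72,11
M57,Satt434,293.93,11
M41,Satt317,465.41,11
M72,Satt568,670.93,11
M15,Satt150,0.00,12
M63,Satt494,345.39,12
M26,Satt201,455.66,12
M22,Satt175,538.75,12
M71,Satt567,588.30,12
M56,Satt427,0.00,13
M12,Satt130,91.38,13
M25,Satt199,190.84,13
M65,Satt505,259.01,13
M76,Satt594,604.40,13
M24,Satt195,0.00,14
M19,Satt161,68.96,14
M38,Satt294,170.89,14
M51,Satt399,255.15,14
M68,Satt529,0.00,15
M29,Satt215,72.32,15
M67,Satt528,417.71,15
M17,Satt158,0.00,16
M27,Satt206,345.39,16
M14,Satt146,0.00,17
M18,Satt160,89.85,17
M54,Satt425,197.04,17
M46,Satt374,273.57,17
M16,Satt155,0.00,18
M39,Satt300,76.49,18
M42,Satt330,0.00,19
M59,Satt451,98.09,19
M2,Satt008,N/A,N/A
M8,Satt085,N/A,N/A
M55,Satt426,N/A,N/A
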